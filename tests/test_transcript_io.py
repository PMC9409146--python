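import numpy as np
import pytest

import cryptoseek as cs
from cryptoseek.orf_enumerator import CryptoDbEntry
from cryptoseek.transcript_io import ConfigError, FormatError, normalize_biotype, validate_design


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestTranscriptFasta:
    def test_gencode_header_fields(self, tmp_path):
        fa = write(
            tmp_path, "t.fa",
            ">ENST0000X.1|ENSG0000Y.1|-|-|TX-201|GENE1|900|lincRNA|\nACGTACGT\n",
        )
        (rec,) = cs.read_transcript_fasta(fa, "gencode")
        assert rec.transcript_id == "ENST0000X.1"
        assert rec.gene_id == "ENSG0000Y.1"
        assert rec.gene_name == "GENE1"
        assert rec.biotype == "lincRNA"

    def test_plain_dialect_defaults_to_other(self, tmp_path):
        fa = write(tmp_path, "t.fa", ">tx1\nACGT\n")
        (rec,) = cs.read_transcript_fasta(fa, "plain")
        assert rec.transcript_id == "tx1"
        assert rec.biotype == "other"

    def test_plain_dialect_with_sidecar(self, tmp_path):
        fa = write(tmp_path, "t.fa", ">tx1\nACGT\n")
        sc = write(tmp_path, "bt.tsv", "tx1\tretained_intron\n")
        (rec,) = cs.read_transcript_fasta(fa, "plain", biotype_sidecar=sc)
        assert rec.biotype == "retained_intron"

    def test_empty_file_gives_empty_list(self, tmp_path, caplog):
        fa = write(tmp_path, "t.fa", "")
        assert cs.read_transcript_fasta(fa, "plain") == []

    def test_short_gencode_header_warns_biotype_other(self, tmp_path, caplog):
        fa = write(tmp_path, "t.fa", ">tx1|g1\nACGT\n")
        with caplog.at_level("WARNING"):
            (rec,) = cs.read_transcript_fasta(fa, "gencode")
        assert rec.biotype == "other"
        assert any("<8 fields" in m for m in caplog.messages)

    def test_u_normalized_and_bad_chars_rejected_per_record(self, tmp_path, caplog):
        fa = write(tmp_path, "t.fa", ">a\nACGU\n>b\nACQT\n>c\nACGTN\n")
        with caplog.at_level("WARNING"):
            recs = cs.read_transcript_fasta(fa, "plain")
        # no silent drops: entries == records + logged rejects
        assert len(recs) == 2 and sum("rejected" in m for m in caplog.messages) == 1
        assert recs[0].sequence == "ACGT"

    def test_unknown_biotype_maps_to_other_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert normalize_biotype("vault_RNA") == "other"
        assert any("vault_RNA" in m for m in caplog.messages)


class TestCryptoDbFasta:
    def _random_entries(self, rng, n):
        entries = []
        for i in range(n):
            aa = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(51, 120))))
            frame = int(rng.integers(0, 3))
            start = frame + 3 * int(rng.integers(0, 50))
            prov = [(f"T{i}_{j}.1", "lincRNA" if j else "retained_intron")
                    for j in range(int(rng.integers(1, 4)))]
            entries.append(
                CryptoDbEntry(
                    orf_id=f"crypt{i:06d}", transcript_id=prov[0][0], frame=frame,
                    nt_start=start, nt_end=start + 3 * (len(aa) + 1), aa_sequence=aa,
                    codon_count=len(aa), biotype=prov[0][1], provenance=prov,
                )
            )
        return entries

    def test_round_trip_identity_on_randomized_entries(self, tmp_path, rng):
        entries = self._random_entries(rng, 1000)
        path = tmp_path / "db.fa"
        cs.write_cryptodb_fasta(entries, path)
        back = cs.read_cryptodb_fasta(path)
        assert len(back) == len(entries)
        for a, b in zip(entries, back):
            assert (a.orf_id, a.frame, a.nt_start, a.nt_end, a.aa_sequence,
                    a.codon_count, a.provenance) == (
                b.orf_id, b.frame, b.nt_start, b.nt_end, b.aa_sequence,
                b.codon_count, b.provenance)

    def test_header_layout(self, tmp_path, rng):
        (e,) = self._random_entries(rng, 1)
        path = tmp_path / "db.fa"
        cs.write_cryptodb_fasta([e], path)
        header = path.read_text().splitlines()[0]
        fields = header[1:].split("|")
        assert fields[0] == e.orf_id
        assert fields[3] == f"f{e.frame}"
        assert int(fields[6]) == e.codon_count

    def test_empty_entry_list_writes_valid_empty_file(self, tmp_path):
        path = tmp_path / "db.fa"
        cs.write_cryptodb_fasta([], path)
        assert cs.read_cryptodb_fasta(path) == []


class TestPsmTable:
    HEADER = "sample_id\tspectrum_id\tpeptide\tq_value\tscore\n"

    def test_well_formed_rows(self, tmp_path):
        p = write(tmp_path, "p.tsv", self.HEADER +
                  "s1\tsp1\tMKLVR\t0.01\t55\ns1\tsp2\tAAAK\t0.02\t44\ns2\tsp3\tWYYR\t0.0\t33\n")
        recs = cs.read_psm_table(p)
        assert len(recs) == 3
        assert all(r.assignment == "unassigned" for r in recs)

    def test_out_of_range_q_value_rejects_file(self, tmp_path):
        p = write(tmp_path, "p.tsv", self.HEADER + "s1\tsp1\tMK\t1.5\t55\n")
        with pytest.raises(FormatError, match="q_value"):
            cs.read_psm_table(p)

    def test_missing_mapped_column_lists_available(self, tmp_path):
        p = write(tmp_path, "p.tsv", self.HEADER + "s1\tsp1\tMK\t0.5\t55\n")
        with pytest.raises(ConfigError, match="available columns"):
            cs.read_psm_table(p, {**cs.transcript_io.DEFAULT_PSM_COLUMNS, "q_value": "qvalue"})

    def test_duplicate_spectrum_pairs_kept_with_warning(self, tmp_path, caplog):
        p = write(tmp_path, "p.tsv", self.HEADER + "s1\tsp1\tMK\t0.1\t55\ns1\tsp1\tAAAK\t0.2\t44\n")
        with caplog.at_level("WARNING"):
            recs = cs.read_psm_table(p)
        assert len(recs) == 2
        assert any("duplicated" in m for m in caplog.messages)


class TestDesign:
    def test_round_trip(self, tmp_path):
        design = cs.make_design(3, 3, cohort="pre_diagnostic", matched=True, seed=5)
        path = tmp_path / "design.tsv"
        cs.write_design_table(design, path)
        assert cs.read_design_table(path) == design

    def test_stratum_must_contain_case_and_control(self):
        design = [
            cs.CohortDesign("a", "case", 3, "S0"),
            cs.CohortDesign("b", "case", 3, "S0"),
            cs.CohortDesign("c", "control", 8, "S1"),
            cs.CohortDesign("d", "case", 3, "S1"),
        ]
        with pytest.raises(FormatError, match="S0"):
            validate_design(design)

    def test_psm_sample_missing_from_design(self):
        design = [cs.CohortDesign("a", "case", 3), cs.CohortDesign("b", "control", 8)]
        with pytest.raises(FormatError, match="missing"):
            validate_design(design, sample_ids=["a", "z"])
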