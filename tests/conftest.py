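import numpy as np
import pytest

import cryptoseek as cs


def make_transcript(seq: str, tid: str = "tx1", biotype: str = "lincRNA") -> cs.TranscriptRecord:
    return cs.TranscriptRecord(tid, "g1", "G1", biotype, seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated dataset exercising the full pipeline once.

    200-codon budget kept small: 30 planted survivor ORFs, 6 decoys, a
    60-protein canonical proteome, and a 10 case / 6 control pooled cohort
    with case-exclusive, fold-change-4 and null plantings.
    """
    specs = [cs.PlantedOrfSpec(f"p{i:02d}", should_survive_purge=(i >= 6)) for i in range(36)]
    transcripts, proteome, manifest = cs.simulate_transcriptome(
        10, planted_orf_specs=specs, seed=11, n_proteins=60
    )
    db = cs.build_orf_database(transcripts)
    kept, report = cs.purge(db, proteome)
    aa_to_orf = {e.aa_sequence: e.orf_id for e in kept}
    planted_kept = [aa_to_orf[o.aa_sequence] for o in manifest.planted_orfs
                    if o.aa_sequence in aa_to_orf]
    effects = {}
    for i, orf_id in enumerate(planted_kept):
        if i < 8:
            effects[orf_id] = ("case_exclusive", 1.0)
        elif i < 16:
            effects[orf_id] = ("fold_change", 4.0)
        else:
            effects[orf_id] = ("null", 1.0)
    design = cs.make_design(10, 6, seed=11)
    psms, cohort_manifest = cs.simulate_psm_cohort(
        kept, design, effects, seed=11, proteome=proteome
    )
    return {
        "transcripts": transcripts,
        "proteome": proteome,
        "manifest": manifest,
        "db": db,
        "kept": kept,
        "purge_report": report,
        "effects": effects,
        "design": design,
        "psms": psms,
    }
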