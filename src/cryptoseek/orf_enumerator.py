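"""Candidate non-canonical ORF enumeration by in-silico translation.

Transcripts are scanned in the three sense-strand frames (inputs are
stranded mRNA, so reverse frames are not considered). A candidate ORF
begins at an AUG, ends at the first in-frame canonical stop codon
(UAA/UGA/UAG), and must exceed a codon-count threshold (default: more than
50 codons, the stop codon not counted). For transcripts annotated as
protein coding, the single largest enumerated ORF — in practice the
annotated coding sequence — is excluded, so that only alternative reading
frames and secondary products remain. Identical amino-acid products from
different transcripts are merged into one database entry carrying full
provenance.

By default one ORF is reported per (frame, stop codon), anchored at the
5'-most in-frame AUG after the previous stop — the standard ORF-caller
convention. ``all_starts=True`` instead reports every qualifying AUG,
which enumerates nested ORFs sharing a stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .transcript_io import TranscriptRecord

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

# codon -> aa from the standard table; stops render '*', any N-containing
# codon renders 'X' even when the ambiguity would resolve (the downstream
# MS matching cannot use ambiguous residues).
_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_TABLE[_stop] = "*"

_VALID_NT = frozenset("ACGTN")


def translate(nt: str) -> str:
    """Translate a nucleotide string in frame 0 under the standard code.

    A trailing partial codon is ignored. Stop codons render as ``*`` and any
    codon containing ``N`` renders as ``X``. Characters outside {A,C,G,T,N}
    raise ``ValueError``.
    """
    if not set(nt) <= _VALID_NT:
        bad = sorted(set(nt) - _VALID_NT)
        raise ValueError(f"invalid nucleotide characters {bad}")
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aa.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(aa)


@dataclass(frozen=True)
class OrfRecord:
    """One enumerated candidate ORF on a transcript.

    Coordinates are 0-based half-open on the transcript as given:
    ``nt_start`` is the A of the AUG, ``nt_end`` is one past the stop codon,
    so ``nt_end - nt_start == 3 * (codon_count + 1)``. ``aa_sequence``
    excludes the stop.
    """

    orf_id: str
    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    codon_count: int
    biotype: str
    gene_name: str = ""

    def __post_init__(self) -> None:
        if not self.aa_sequence.startswith("M"):
            raise ValueError(f"{self.orf_id}: ORF must start with M")
        if self.codon_count != len(self.aa_sequence):
            raise ValueError(f"{self.orf_id}: codon_count != len(aa_sequence)")
        if self.nt_end - self.nt_start != 3 * (self.codon_count + 1):
            raise ValueError(f"{self.orf_id}: coordinate span inconsistent with codon_count")


@dataclass(frozen=True)
class EnumerationConfig:
    """Enumeration rules.

    min_codons : exclusive threshold on the amino-acid length (stop codon
        not counted); the default keeps ORFs of more than 50 codons.
    all_starts : report every in-frame AUG per stop instead of the 5'-most.
    drop_ambiguous : discard ORFs whose product contains ``X``.
    """

    min_codons: int = 50
    all_starts: bool = False
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if self.min_codons < 1:
            raise ValueError("min_codons must be >= 1")


@dataclass
class CryptoDbEntry:
    """A candidate cryptoprotein: an ORF (or merged identical ORFs) with provenance.

    ``provenance`` lists every (transcript_id, biotype) source of the same
    amino-acid product; the first pair is the representative whose
    coordinates are stored. ``purge_status`` is set by the homology purge:
    entries with any status other than ``kept`` never appear in the emitted
    database.
    """

    orf_id: str
    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    codon_count: int
    biotype: str
    gene_name: str = ""
    provenance: list[tuple[str, str]] = field(default_factory=list)
    purge_status: str = "kept"
    purge_evidence: str | None = None

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [(self.transcript_id, self.biotype)]


def _scan_orfs(t: TranscriptRecord, cfg: EnumerationConfig, apply_length_filter: bool) -> list[OrfRecord]:
    """Scan the three sense frames for AUG...stop ORFs.

    Walks each frame codon-by-codon tracking open AUG positions; at a stop,
    emits the 5'-most open start (or all of them under ``all_starts``) and
    resets. ORFs without an in-transcript stop are discarded.
    """
    seq = t.sequence
    out: list[OrfRecord] = []
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_starts:
                    starts = open_starts if cfg.all_starts else open_starts[:1]
                    for start in starts:
                        aa = translate(seq[start:pos])
                        if cfg.drop_ambiguous and "X" in aa:
                            continue
                        if apply_length_filter and len(aa) <= cfg.min_codons:
                            continue
                        out.append(
                            OrfRecord(
                                orf_id=f"{t.transcript_id}:f{frame}:{start}-{pos + 3}",
                                transcript_id=t.transcript_id,
                                frame=frame,
                                nt_start=start,
                                nt_end=pos + 3,
                                aa_sequence=aa,
                                codon_count=len(aa),
                                biotype=t.biotype,
                                gene_name=t.gene_name,
                            )
                        )
                    open_starts = []
            elif codon == "ATG" and (cfg.all_starts or not open_starts):
                open_starts.append(pos)
    return out


def enumerate_orfs(t: TranscriptRecord, cfg: EnumerationConfig | None = None) -> list[OrfRecord]:
    """Enumerate candidate ORFs on one transcript under the configured rules."""
    cfg = cfg or EnumerationConfig()
    return _scan_orfs(t, cfg, apply_length_filter=True)


def build_orf_database(
    transcripts: Iterable[TranscriptRecord], cfg: EnumerationConfig | None = None
) -> list[CryptoDbEntry]:
    """Enumerate ORFs over a transcriptome and assemble the pre-purge database.

    For each transcript annotated ``protein_coding`` the single largest
    enumerated ORF is removed before the length filter is applied (ties
    broken by 5'-most start, then lowest frame) — this drops the annotated
    coding product so only non-canonical candidates remain. Identical
    amino-acid sequences across transcripts are merged into one entry whose
    provenance lists every source. Entry ids are assigned sequentially in
    input order.
    """
    cfg = cfg or EnumerationConfig()
    by_aa: dict[str, CryptoDbEntry] = {}
    biotype_counts: dict[str, int] = {}
    for t in transcripts:
        if t.biotype == "protein_coding":
            orfs = _scan_orfs(t, cfg, apply_length_filter=False)
            if orfs:
                largest = max(orfs, key=lambda o: (o.codon_count, -o.nt_start, -o.frame))
                orfs = [o for o in orfs if o is not largest]
            orfs = [o for o in orfs if o.codon_count > cfg.min_codons]
        else:
            orfs = enumerate_orfs(t, cfg)
        for o in orfs:
            existing = by_aa.get(o.aa_sequence)
            if existing is None:
                by_aa[o.aa_sequence] = CryptoDbEntry(
                    orf_id="",  # assigned after dedupe
                    transcript_id=o.transcript_id,
                    frame=o.frame,
                    nt_start=o.nt_start,
                    nt_end=o.nt_end,
                    aa_sequence=o.aa_sequence,
                    codon_count=o.codon_count,
                    biotype=o.biotype,
                    gene_name=o.gene_name,
                    provenance=[(o.transcript_id, o.biotype)],
                )
            else:
                existing.provenance.append((o.transcript_id, o.biotype))
    entries = list(by_aa.values())
    width = max(6, len(str(len(entries))))
    for i, e in enumerate(entries, start=1):
        e.orf_id = f"crypt{i:0{width}d}"
        biotype_counts[e.biotype] = biotype_counts.get(e.biotype, 0) + 1
    logger.info("ORF database: %d entries; per-biotype counts: %s", len(entries), biotype_counts)
    return entries
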