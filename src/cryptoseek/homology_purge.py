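"""Homology purge: remove candidate ORFs resembling the canonical proteome.

Three modes reproduce the "no known homology" filter at different
fidelity/cost points:

``exact``
    An entry is removed when any of its fully tryptic peptides of length
    >= ``kmer_len`` occurs verbatim (I/L folded by default) in any
    canonical protein. This is the MS-relevant criterion — a candidate
    whose observable peptides are indistinguishable from canonical ones
    can never be confidently identified — and is the default.
``align``
    Local alignment (BLOSUM62, affine gaps) of each entry against each
    canonical protein, removed when the Karlin-Altschul E-value falls at or
    below the threshold. Reproduces a BLASTP-style screen without an
    external aligner.
``import``
    Consume a 12-column BLAST tabular file produced by an external aligner
    run against any protein database, removing entries with a hit at or
    below the E-value threshold.

Isoleucine and leucine are isobaric in mass spectrometry, so peptide
matching folds I onto L by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from pyteomics import parser as pt_parser

from .orf_enumerator import CryptoDbEntry

logger = logging.getLogger(__name__)

TRYPSIN_RULE = r"[KR](?!P)"  # cleave after K/R except before P

#: Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1,
#: the BLASTP defaults.
_BLOSUM62_GAPPED = {"lambda": 0.267, "K": 0.041}


def fold_il(seq: str) -> str:
    """Collapse isoleucine onto leucine (isobaric residues)."""
    return seq.replace("I", "L")


def tryptic_peptides(aa: str, min_len: int = 1) -> set[str]:
    """Fully tryptic peptides (zero missed cleavages) of length >= min_len.

    Cleaves after K or R except when the next residue is P.
    """
    return set(pt_parser.cleave(aa, TRYPSIN_RULE, missed_cleavages=0, min_length=min_len))


@dataclass(frozen=True)
class PurgeParams:
    """Parameters of the homology purge.

    kmer_len : minimum tryptic-peptide length considered matchable in exact
        mode (shorter peptides are uninformative in MS).
    il_equivalence : fold I onto L before matching.
    matrix / gap_open / gap_extend : local-alignment scoring (align mode).
    e_threshold : remove when E <= this value (a significant alignment
        means homology).
    search_space : residue count used for E-value calibration; when None the
        supplied proteome's total residue count is used.
    min_coverage : optional fraction of the entry that must be aligned for a
        removal in align mode (None = no coverage requirement).
    """

    mode: str = "exact"
    kmer_len: int = 8
    il_equivalence: bool = True
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    e_threshold: float = 0.01
    search_space: int | None = None
    min_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "align", "import"):
            raise ValueError(f"unknown purge mode {self.mode!r}")
        if self.kmer_len < 5:
            raise ValueError("kmer_len must be >= 5")
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be > 0")


def _removal_report(removed: list[tuple[CryptoDbEntry, str, str]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "orf_id": [e.orf_id for e, _, _ in removed],
            "status": [s for _, s, _ in removed],
            "evidence": [ev for _, _, ev in removed],
        }
    )


def _purge_exact(
    entries: Sequence[CryptoDbEntry], proteome: Sequence[tuple[str, str]], params: PurgeParams
) -> tuple[list[CryptoDbEntry], pd.DataFrame]:
    fold = fold_il if params.il_equivalence else (lambda s: s)
    folded = [(acc, fold(seq)) for acc, seq in proteome]
    # substring queries against one separator-joined text; '|' is outside
    # the amino-acid alphabet so no peptide can straddle a boundary
    text = "|".join(seq for _, seq in folded)
    kept: list[CryptoDbEntry] = []
    removed: list[tuple[CryptoDbEntry, str, str]] = []
    for e in entries:
        hit: tuple[str, str] | None = None
        for pep in sorted(tryptic_peptides(fold(e.aa_sequence), params.kmer_len)):
            if pep in text:
                acc = next(a for a, seq in folded if pep in seq)
                hit = (acc, pep)
                break
        if hit is None:
            kept.append(e)
        else:
            e.purge_status = "removed_exact"
            e.purge_evidence = f"{hit[0]}:peptide={hit[1]}"
            removed.append((e, e.purge_status, e.purge_evidence))
    return kept, _removal_report(removed)


def _purge_align(
    entries: Sequence[CryptoDbEntry], proteome: Sequence[tuple[str, str]], params: PurgeParams
) -> tuple[list[CryptoDbEntry], pd.DataFrame]:
    from Bio import Align
    from Bio.Align import substitution_matrices

    try:
        matrix = substitution_matrices.load(params.matrix)
    except FileNotFoundError as exc:
        raise ValueError(
            f"unknown substitution matrix {params.matrix!r}; "
            f"available: {substitution_matrices.load()}"
        ) from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    ka = _BLOSUM62_GAPPED
    n_db = params.search_space or sum(len(s) for _, s in proteome)
    kept: list[CryptoDbEntry] = []
    removed: list[tuple[CryptoDbEntry, str, str]] = []
    for e in entries:
        best: tuple[float, str, float] | None = None  # (evalue, acc, score)
        m = len(e.aa_sequence)
        for acc, seq in proteome:
            aln = aligner.align(e.aa_sequence, seq)
            score = aln.score
            if params.min_coverage is not None:
                top = aln[0]
                q0, q1 = top.aligned[0][0][0], top.aligned[0][-1][1]
                if (q1 - q0) / m < params.min_coverage:
                    continue
            evalue = ka["K"] * m * n_db * math.exp(-ka["lambda"] * score)
            if best is None or evalue < best[0]:
                best = (evalue, acc, score)
        if best is not None and best[0] <= params.e_threshold:
            e.purge_status = "removed_align"
            e.purge_evidence = f"{best[1]}:score={best[2]:.1f}:E={best[0]:.3g}"
            removed.append((e, e.purge_status, e.purge_evidence))
        else:
            kept.append(e)
    return kept, _removal_report(removed)


def purge(
    entries: Sequence[CryptoDbEntry],
    proteome: Sequence[tuple[str, str]],
    params: PurgeParams | None = None,
) -> tuple[list[CryptoDbEntry], pd.DataFrame]:
    """Remove entries with detectable homology to the canonical proteome.

    Returns the kept entries and a removal report (orf_id, status,
    evidence). Identical inputs and params yield byte-identical reports.
    """
    params = params or PurgeParams()
    if not proteome:
        raise ValueError("canonical proteome is empty")
    if params.mode == "exact":
        kept, report = _purge_exact(entries, proteome, params)
    elif params.mode == "align":
        kept, report = _purge_align(entries, proteome, params)
    else:
        raise ValueError("import mode requires import_alignment_results with a results file")
    logger.info("purge (%s): %d kept, %d removed", params.mode, len(kept), len(report))
    return kept, report


BLAST_TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def import_alignment_results(
    entries: Sequence[CryptoDbEntry], tabular_path: str | Path, e_threshold: float = 0.01
) -> tuple[list[CryptoDbEntry], pd.DataFrame]:
    """Apply an external aligner's 12-column tabular output as the purge.

    Entries with any hit at ``evalue <= e_threshold`` are removed
    (evidence = best such row); entries absent from the file are kept.
    """
    try:
        df = pd.read_csv(
            tabular_path, sep="\t", header=None, names=BLAST_TABULAR_COLUMNS, comment="#"
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"unparseable alignment results in {tabular_path}: {exc}") from exc
    df["evalue"] = pd.to_numeric(df["evalue"], errors="coerce")
    bad_rows = df.index[df["evalue"].isna() | df["qseqid"].isna() | df["sseqid"].isna()]
    if len(bad_rows):
        raise ValueError(f"unparseable alignment row at {tabular_path} line {int(bad_rows[0]) + 1}")
    best_hits = (
        df[df["evalue"] <= e_threshold].sort_values("evalue").groupby("qseqid").first()
    )
    kept: list[CryptoDbEntry] = []
    removed: list[tuple[CryptoDbEntry, str, str]] = []
    for e in entries:
        if e.orf_id in best_hits.index:
            row = best_hits.loc[e.orf_id]
            e.purge_status = "removed_import"
            e.purge_evidence = f"{row['sseqid']}:E={row['evalue']:.3g}:bitscore={row['bitscore']}"
            removed.append((e, e.purge_status, e.purge_evidence))
        else:
            kept.append(e)
    return kept, _removal_report(removed)


def audit_exact_purge(
    kept: Sequence[CryptoDbEntry], proteome: Sequence[tuple[str, str]], params: PurgeParams
) -> int:
    """Count residual tryptic >=kmer_len matches of kept entries vs the proteome.

    Zero after an exact-mode purge; exposed so pipelines can assert it.
    """
    fold = fold_il if params.il_equivalence else (lambda s: s)
    text = "|".join(fold(seq) for _, seq in proteome)
    return sum(
        1
        for e in kept
        for pep in tryptic_peptides(fold(e.aa_sequence), params.kmer_len)
        if pep in text
    )
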