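"""Two-pass assignment of peptide identifications and spectral-count quantification.

Pass one removes every PSM whose peptide occurs in the canonical proteome
(I/L folded by default — isobaric residues are indistinguishable by MS).
Pass two maps the remaining peptides onto the cryptoprotein database:
a PSM is assigned when it clears the FDR threshold and its peptide occurs
in exactly one database entry; multi-mapping peptides are dropped (counted,
never double-counted). Abundance is then implied by spectral counting —
the per-sample sum of assigned PSMs — and cryptoproteins are retained only
when they reach the minimum total PSM count and are detected in the minimum
number of samples within a cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .homology_purge import fold_il
from .orf_enumerator import CryptoDbEntry
from .transcript_io import CohortDesign, PsmRecord, validate_design

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Identification and selection filters.

    fdr_max : strict upper bound on the peptide q-value (default 0.10,
        i.e. FDR < 10%).
    psm_min : minimum summed spectral count per cryptoprotein (default 5).
    min_samples : minimum number of samples with a non-zero count, within a
        cohort (default 2).
    """

    fdr_max: float = 0.10
    psm_min: int = 5
    min_samples: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")
        if self.psm_min < 1 or self.min_samples < 1:
            raise ValueError("psm_min and min_samples must be >= 1")


@dataclass
class AssignmentSummary:
    """Bookkeeping for the conservation identity.

    canonical + crypto + dropped_fdr + dropped_ambiguous + unmatched equals
    the number of input PSMs.
    """

    canonical: int = 0
    crypto: int = 0
    dropped_fdr: int = 0
    dropped_ambiguous: int = 0
    unmatched: int = 0

    @property
    def total(self) -> int:
        return self.canonical + self.crypto + self.dropped_fdr + self.dropped_ambiguous + self.unmatched


def partition_canonical(
    psms: Sequence[PsmRecord], proteome: Sequence[tuple[str, str]], il_equivalence: bool = True
) -> list[PsmRecord]:
    """First pass: mark PSMs whose peptide occurs in any canonical protein.

    Matching is substring occurrence, I/L folded when enabled. The
    partition is exhaustive and exclusive: every PSM ends up ``canonical``
    or ``unassigned``.
    """
    fold = fold_il if il_equivalence else (lambda s: s)
    text = "|".join(fold(seq) for _, seq in proteome)
    cache: dict[str, bool] = {}
    for p in psms:
        pep = fold(p.peptide)
        hit = cache.get(pep)
        if hit is None:
            hit = cache[pep] = pep in text
        p.assignment = "canonical" if hit else "unassigned"
    return list(psms)


def assign_and_filter(
    psms: Sequence[PsmRecord],
    db: Sequence[CryptoDbEntry],
    cfg: FilterConfig | None = None,
    il_equivalence: bool = True,
) -> tuple[list[PsmRecord], dict[str, str], AssignmentSummary]:
    """Second pass: map FDR-passing unassigned PSMs onto the cryptoDB.

    Returns the crypto-assigned PSMs, a mapping peptide -> orf_id for the
    uniquely assigned peptides, and the conservation summary. Canonical
    PSMs are never re-assigned; PSMs whose peptide occurs in more than one
    entry are dropped with a logged count.
    """
    cfg = cfg or FilterConfig()
    fold = fold_il if il_equivalence else (lambda s: s)
    if not db:
        logger.warning("empty cryptoDB: no crypto assignments possible")
    folded_db = [(e.orf_id, fold(e.aa_sequence)) for e in db]
    summary = AssignmentSummary()
    assigned: list[PsmRecord] = []
    pep_to_orf: dict[str, str] = {}
    cache: dict[str, list[str]] = {}
    for p in psms:
        if p.assignment == "canonical":
            summary.canonical += 1
            continue
        if not (p.q_value < cfg.fdr_max):
            summary.dropped_fdr += 1
            continue
        pep = fold(p.peptide)
        hits = cache.get(pep)
        if hits is None:
            hits = cache[pep] = [orf_id for orf_id, seq in folded_db if pep in seq]
        if len(hits) == 1:
            p.assignment = "crypto"
            pep_to_orf[p.peptide] = hits[0]
            assigned.append(p)
            summary.crypto += 1
        elif len(hits) > 1:
            summary.dropped_ambiguous += 1
        else:
            summary.unmatched += 1
    if summary.dropped_ambiguous:
        logger.info("%d PSMs dropped as multi-mapping across cryptoDB entries", summary.dropped_ambiguous)
    return assigned, pep_to_orf, summary


@dataclass
class QuantMatrix:
    """Cryptoprotein x sample spectral-count matrix after selection filters.

    ``counts`` has orf_ids as the index and sample_ids as columns (integer
    PSM counts); ``row_meta`` carries total_psm, n_samples_detected, the
    peptide set, and which cohorts the row passed selection in.
    """

    counts: pd.DataFrame
    row_meta: pd.DataFrame

    def validate(self) -> None:
        totals = self.counts.sum(axis=1)
        detected = (self.counts > 0).sum(axis=1)
        if not (totals == self.row_meta["total_psm"]).all():
            raise AssertionError("total_psm inconsistent with row sums")
        if not (detected == self.row_meta["n_samples_detected"]).all():
            raise AssertionError("n_samples_detected inconsistent with non-zero cells")


def quantify_and_select(
    crypto_psms: Sequence[PsmRecord],
    pep_to_orf: dict[str, str],
    design: Sequence[CohortDesign],
    cfg: FilterConfig | None = None,
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Spectral-count quantification with per-cohort selection filters.

    cell(i, s) = number of crypto-assigned PSMs of entry i in sample s.
    A row is retained when, within at least one cohort, its summed count is
    >= psm_min and it is detected in >= min_samples samples; the per-cohort
    pass flags are recorded in ``row_meta``. Also returns a report of the
    dropped rows.
    """
    cfg = cfg or FilterConfig()
    validate_design(design, sample_ids=[p.sample_id for p in crypto_psms])
    sample_ids = [d.sample_id for d in design]
    cohorts = sorted({d.cohort for d in design})
    cohort_samples = {c: [d.sample_id for d in design if d.cohort == c] for c in cohorts}

    rows = sorted({pep_to_orf[p.peptide] for p in crypto_psms})
    long = pd.DataFrame(
        {
            "orf_id": [pep_to_orf[p.peptide] for p in crypto_psms],
            "sample_id": [p.sample_id for p in crypto_psms],
        }
    )
    counts = (
        pd.crosstab(long["orf_id"], long["sample_id"])
        .reindex(index=rows, columns=sample_ids, fill_value=0)
        .astype(np.int64)
        .rename_axis(index="orf_id", columns=None)
    )
    peptides: dict[str, set[str]] = {r: set() for r in rows}
    for p in crypto_psms:
        peptides[pep_to_orf[p.peptide]].add(p.peptide)

    pass_flags = pd.DataFrame(False, index=counts.index, columns=cohorts)
    for c in cohorts:
        sub = counts[cohort_samples[c]]
        pass_flags[c] = (sub.sum(axis=1) >= cfg.psm_min) & ((sub > 0).sum(axis=1) >= cfg.min_samples)
    keep = pass_flags.any(axis=1)

    dropped = pd.DataFrame(
        {
            "orf_id": counts.index[~keep],
            "total_psm": counts.sum(axis=1)[~keep],
            "n_samples_detected": (counts > 0).sum(axis=1)[~keep],
            "reason": "below psm_min/min_samples in every cohort",
        }
    ).reset_index(drop=True)

    kept_counts = counts[keep]
    row_meta = pd.DataFrame(
        {
            "total_psm": kept_counts.sum(axis=1),
            "n_samples_detected": (kept_counts > 0).sum(axis=1),
            "peptides": [";".join(sorted(peptides[r])) for r in kept_counts.index],
        },
        index=kept_counts.index,
    )
    for c in cohorts:
        row_meta[f"pass_{c}"] = pass_flags.loc[keep, c]
    qm = QuantMatrix(counts=kept_counts, row_meta=row_meta)
    qm.validate()
    logger.info("quantified %d cryptoproteins (%d dropped by selection filters)", len(kept_counts), len(dropped))
    return qm, dropped


def assert_exclusion_soundness(
    crypto_psms: Sequence[PsmRecord], proteome: Sequence[tuple[str, str]], il_equivalence: bool = True
) -> None:
    """Assert no crypto-assigned peptide occurs (I/L folded) in the canonical proteome."""
    fold = fold_il if il_equivalence else (lambda s: s)
    text = "|".join(fold(seq) for _, seq in proteome)
    offenders = sorted({p.peptide for p in crypto_psms if fold(p.peptide) in text})
    if offenders:
        raise AssertionError(f"crypto-assigned peptides match the canonical proteome: {offenders[:5]}")
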