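"""Case/control statistics for cryptoprotein hit calling.

Newly diagnosed cohorts are screened by fold-change and case-exclusivity:
a cryptoprotein is a hit when it is quantified exclusively in case pools
or when its mean spectral count exceeds the control mean by more than the
fold-change threshold (default 2). Matched pre-diagnostic cohorts are
screened by odds ratios on binary detection: logistic regression for an
unmatched design, conditional logistic regression (stratum-conditional
likelihood) for matched strata; a hit requires OR >= 2 with one-sided
p < 0.05 in the elevated direction. Wilcoxon rank-sum p-values (exact with
mid-ranks for small cohorts) are reported alongside.

The statistical unit is the pool, and the default predictor coding is
binary detection (count > 0) per pool: presence/absence is what a pooled
Ig-bound screen measures reliably, and it keeps zero-inflated spectral
counts out of the linear predictor. Abundance coding is available as an
option. Zero cells are handled by the Haldane-Anscombe 0.5 correction with
an explicit flag, since markers absent in all controls are otherwise
inestimable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .transcript_io import CohortDesign
from .twopass_assign import QuantMatrix

logger = logging.getLogger(__name__)

CASE_EXCLUSIVE = "case_exclusive"


@dataclass(frozen=True)
class StatConfig:
    """Thresholds and numerical options for hit calling.

    fc_threshold : fold-change hit threshold (strict, default 2).
    or_threshold : odds-ratio hit threshold (inclusive, default 2).
    alpha : one-sided significance level for the OR screen (default 0.05).
    zero_cell_correction : apply the Haldane-Anscombe 0.5 correction when a
        detection table has a zero cell (flagged).
    pseudocount : when set, zero group means are replaced by this value so a
        finite fold-change is always reported (case-exclusivity is still
        flagged from the raw zeros).
    """

    fc_threshold: float = 2.0
    or_threshold: float = 2.0
    alpha: float = 0.05
    zero_cell_correction: bool = True
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.or_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must be in (0, 0.5]")


def _split_samples(design: Sequence[CohortDesign]) -> tuple[list[str], list[str]]:
    cases = [d.sample_id for d in design if d.group == "case"]
    controls = [d.sample_id for d in design if d.group == "control"]
    if not cases or not controls:
        raise ValueError("design must contain at least one case and one control sample")
    return cases, controls


def fold_change_table(
    qm: QuantMatrix, design: Sequence[CohortDesign], cfg: StatConfig | None = None
) -> pd.DataFrame:
    """Per-cryptoprotein fold-change and exclusivity status.

    fc = mean(case counts) / mean(control counts). A control mean of zero
    with a positive case mean is the sentinel status ``case_exclusive``
    (no division); both means zero is ``not_evaluable``.
    """
    cfg = cfg or StatConfig()
    cases, controls = _split_samples(design)
    case_mean = qm.counts[cases].mean(axis=1)
    control_mean = qm.counts[controls].mean(axis=1)

    fc = pd.Series(np.nan, index=qm.counts.index)
    status = pd.Series("evaluable", index=qm.counts.index)
    exclusive = (control_mean == 0) & (case_mean > 0)
    neither = (control_mean == 0) & (case_mean == 0)
    status[exclusive] = CASE_EXCLUSIVE
    status[neither] = "not_evaluable"
    ok = ~(exclusive | neither)
    if cfg.pseudocount is not None:
        cm = control_mean.where(control_mean > 0, cfg.pseudocount)
        am = case_mean.where(case_mean > 0, cfg.pseudocount)
        fc = am / cm
    else:
        fc[ok] = case_mean[ok] / control_mean[ok]
    out = pd.DataFrame(
        {
            "case_mean": case_mean,
            "control_mean": control_mean,
            "fc": fc,
            "status": status,
            "case_exclusive": exclusive,
            "fc_gt2": fc.gt(cfg.fc_threshold).fillna(False) & ~exclusive,
        }
    )
    return out


def _table_2x2(detected: pd.Series, case_ids: list[str], control_ids: list[str]) -> tuple[int, int, int, int]:
    a = int(detected[case_ids].sum())          # cases, detected
    b = int(detected[control_ids].sum())       # controls, detected
    c = len(case_ids) - a                      # cases, not detected
    d = len(control_ids) - b                   # controls, not detected
    return a, b, c, d


def _wald_row(log_or: float, se: float) -> tuple[float, tuple[float, float], float]:
    z = log_or / se
    ci = (float(np.exp(log_or - 1.959963984540054 * se)), float(np.exp(log_or + 1.959963984540054 * se)))
    return float(np.exp(log_or)), ci, float(sps.norm.sf(z))


def _logistic_row(a: int, b: int, c: int, d: int, cfg: StatConfig) -> dict:
    """Logistic OR of case status on binary detection from the 2x2 table.

    For a single binary predictor the ML estimate is the cross-product
    ratio ad/bc; the fit is done by maximum likelihood and the correction
    path handles separation/zero cells.
    """
    flags: list[str] = []
    if (a + b) == 0 or (c + d) == 0:
        return {"or_hat": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_one_sided": np.nan,
                "flags": "not_estimable"}
    if min(a, b, c, d) == 0:
        if not cfg.zero_cell_correction:
            return {"or_hat": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_one_sided": np.nan,
                    "flags": "not_estimable"}
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        log_or = np.log(aa * dd / (bb * cc))
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        flags.append("separation_corrected")
    else:
        y = np.repeat([1, 1, 0, 0], [a, c, b, d])
        x = np.repeat([1, 0, 1, 0], [a, c, b, d])
        try:
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            log_or, se = float(fit.params[1]), float(fit.bse[1])
        except (PerfectSeparationError, np.linalg.LinAlgError):  # pragma: no cover - guarded above
            return {"or_hat": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_one_sided": np.nan,
                    "flags": "not_estimable"}
    or_hat, ci, p = _wald_row(log_or, se)
    return {"or_hat": or_hat, "ci_low": ci[0], "ci_high": ci[1], "p_one_sided": p,
            "flags": ";".join(flags)}


def conditional_logit_binary(
    y: np.ndarray, x: np.ndarray, strata: Sequence[Sequence[int]],
    tol: float = 1e-12, max_iter: int = 100,
) -> tuple[float, float]:
    """Conditional-logistic MLE for a binary exposure over matched strata.

    Maximizes the stratum-conditional likelihood by Newton iteration. For a
    binary exposure the per-stratum denominator depends only on the number
    of exposed subjects j drawn into the case set, with hypergeometric
    multiplicities C(k, j) C(n-k, m-j); the score and information are the
    mean and variance of j under the tilted distribution. For 1:1 matching
    this reduces to the discordant-pair ratio.

    Returns (log OR, Wald SE). Raises ``FloatingPointError`` on separation
    (the estimate diverges).
    """
    from math import comb

    stratum_terms: list[tuple[int, np.ndarray, np.ndarray]] = []
    t_total = 0
    for ix in strata:
        ix = list(ix)
        m = int(y[ix].sum())
        n = len(ix)
        k = int(x[ix].sum())
        if m == 0 or m == n or k == 0 or k == n:
            continue  # concordant or uninformative: contributes a constant
        t_total += int(x[[i for i in ix if y[i] == 1]].sum())
        j_lo, j_hi = max(0, m - (n - k)), min(m, k)
        js = np.arange(j_lo, j_hi + 1)
        ws = np.array([comb(k, j) * comb(n - k, m - j) for j in js], dtype=float)
        stratum_terms.append((m, js, ws))
    if not stratum_terms:
        raise FloatingPointError("no informative strata")
    beta = 0.0
    for _ in range(max_iter):
        score = float(t_total)
        info = 0.0
        for _, js, ws in stratum_terms:
            w = ws * np.exp(beta * js)
            w /= w.sum()
            mean_j = float(js @ w)
            score -= mean_j
            info += float((js - mean_j) ** 2 @ w)
        if info <= 1e-12 or abs(beta) > 30:
            raise FloatingPointError("conditional likelihood is monotone (separation)")
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    else:
        raise FloatingPointError("Newton iteration did not converge")
    info = 0.0
    for _, js, ws in stratum_terms:
        w = ws * np.exp(beta * js)
        w /= w.sum()
        mean_j = float(js @ w)
        info += float((js - mean_j) ** 2 @ w)
    return beta, float(1.0 / np.sqrt(info))


def _conditional_row(
    detected: pd.Series, design: Sequence[CohortDesign], cfg: StatConfig
) -> dict:
    """Conditional-logistic OR of case status on detection within matched strata.

    The stratum-conditional likelihood eliminates per-stratum nuisance
    intercepts; for binary detection in 1:1 matching the MLE is the
    discordant-pair ratio, which also serves as the correction path under
    separation.
    """
    if any(d.stratum_id is None for d in design):
        raise ValueError("conditional method requires stratum_id on every sample")
    y = np.array([1 if d.group == "case" else 0 for d in design])
    x = np.array([float(detected[d.sample_id]) for d in design])

    strata: dict[str, list[int]] = {}
    for i, d in enumerate(design):
        strata.setdefault(d.stratum_id, []).append(i)
    stratum_ix = list(strata.values())
    one_to_one = all(len(ix) == 2 for ix in stratum_ix)
    n10 = n01 = 0
    if one_to_one:
        for ix in stratum_ix:
            ci = next(i for i in ix if y[i] == 1)
            ki = next(i for i in ix if y[i] == 0)
            if x[ci] > x[ki]:
                n10 += 1
            elif x[ki] > x[ci]:
                n01 += 1
    binary = set(np.unique(x)) <= {0.0, 1.0}
    try:
        if binary:
            log_or, se = conditional_logit_binary(y, x, stratum_ix)
        else:
            groups = np.array([d.stratum_id for d in design])
            fit = ConditionalLogit(y, x[:, None], groups=groups).fit(disp=0)
            log_or, se = float(fit.params[0]), float(fit.bse[0])
            if not (np.isfinite(log_or) and np.isfinite(se) and se > 0):
                raise FloatingPointError("conditional fit did not converge")
        or_hat, ci, p = _wald_row(log_or, se)
        return {"or_hat": or_hat, "ci_low": ci[0], "ci_high": ci[1],
                "p_one_sided": p, "flags": ""}
    except (FloatingPointError, PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        pass
    if one_to_one and (n10 + n01) > 0 and cfg.zero_cell_correction:
        log_or = np.log((n10 + 0.5) / (n01 + 0.5))
        se = np.sqrt(1 / (n10 + 0.5) + 1 / (n01 + 0.5))
        or_hat, ci, p = _wald_row(log_or, se)
        return {"or_hat": or_hat, "ci_low": ci[0], "ci_high": ci[1], "p_one_sided": p,
                "flags": "separation_corrected"}
    return {"or_hat": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_one_sided": np.nan,
            "flags": "not_estimable"}


def odds_ratio(
    qm: QuantMatrix,
    design: Sequence[CohortDesign],
    method: str = "logistic",
    cfg: StatConfig | None = None,
    predictor: str = "detection",
) -> pd.DataFrame:
    """Per-cryptoprotein odds ratio with Wald 95% CI and one-sided p (OR > 1).

    ``logistic`` fits group ~ predictor by maximum likelihood; ``conditional``
    maximizes the stratum-conditional likelihood over matched strata.
    The default predictor is binary detection per pool; ``abundance`` uses
    log1p(count) instead (the OR is then per log-count unit).
    """
    cfg = cfg or StatConfig()
    if method not in ("logistic", "conditional"):
        raise ValueError(f"unknown method {method!r}")
    if predictor not in ("detection", "abundance"):
        raise ValueError(f"unknown predictor {predictor!r}")
    cases, controls = _split_samples(design)
    rows = []
    for orf_id, counts in qm.counts.iterrows():
        if predictor == "detection":
            pred = (counts > 0).astype(int)
        else:
            pred = np.log1p(counts)
        if method == "logistic":
            if predictor == "detection":
                row = _logistic_row(*_table_2x2(pred, cases, controls), cfg)
            else:
                row = _logistic_abundance_row(pred, design)
        else:
            row = _conditional_row(pred, design, cfg)
        row["orf_id"] = orf_id
        rows.append(row)
    out = pd.DataFrame(rows).set_index("orf_id")
    out["or_hit"] = (
        out["or_hat"].ge(cfg.or_threshold).fillna(False)
        & out["p_one_sided"].lt(cfg.alpha).fillna(False)
    )
    return out


def _logistic_abundance_row(pred: pd.Series, design: Sequence[CohortDesign]) -> dict:
    y = np.array([1 if d.group == "case" else 0 for d in design])
    x = np.array([pred[d.sample_id] for d in design], dtype=float)
    if np.allclose(x, x[0]):
        return {"or_hat": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_one_sided": np.nan,
                "flags": "not_estimable"}
    try:
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return {"or_hat": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_one_sided": np.nan,
                "flags": "not_estimable"}
    or_hat, ci, p = _wald_row(float(fit.params[1]), float(fit.bse[1]))
    return {"or_hat": or_hat, "ci_low": ci[0], "ci_high": ci[1], "p_one_sided": p, "flags": ""}


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

_EXACT_N_MAX = 20


def _exact_ranksum_p(case_vals: np.ndarray, control_vals: np.ndarray) -> float:
    """Exact two-sided rank-sum p with mid-ranks for ties.

    The null distribution of the case rank-sum W over all C(n, n1) group
    assignments is built by dynamic programming over the (tie-adjusted)
    rank multiset; the two-sided p is P(|W - E[W]| >= |w_obs - E[W]|).
    """
    values = np.concatenate([case_vals, control_vals])
    n1, n = len(case_vals), len(values)
    ranks = sps.rankdata(values)  # mid-ranks
    int_ranks = np.round(ranks * 2).astype(int)  # half-units -> integers
    w_obs = int(int_ranks[:n1].sum())
    total = int(int_ranks.sum())
    # ways[k][s] = number of k-subsets of ranks with sum s
    ways = [np.zeros(total + 1, dtype=float) for _ in range(n1 + 1)]
    ways[0][0] = 1.0
    for r in int_ranks:
        for k in range(min(n1, n) - 1, -1, -1):
            w = ways[k]
            ways[k + 1][r:] += w[: total + 1 - r]
    dist = ways[n1]
    n_total = dist.sum()
    mean_w = n1 * total / n
    dev = abs(w_obs - mean_w)
    support = np.arange(total + 1)
    p = dist[np.abs(support - mean_w) >= dev - 1e-9].sum() / n_total
    return float(min(1.0, p))


def wilcoxon_pvalues(qm: QuantMatrix, design: Sequence[CohortDesign]) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p-value per cryptoprotein (case vs control).

    Exact distribution with mid-ranks for ties when the combined sample
    size is <= 20; otherwise the normal approximation with tie correction.
    """
    cases, controls = _split_samples(design)
    out = {}
    for orf_id, counts in qm.counts.iterrows():
        cv = counts[cases].to_numpy(dtype=float)
        kv = counts[controls].to_numpy(dtype=float)
        if len(cv) + len(kv) <= _EXACT_N_MAX:
            out[orf_id] = _exact_ranksum_p(cv, kv)
        else:
            out[orf_id] = float(
                sps.mannwhitneyu(cv, kv, alternative="two-sided", method="asymptotic").pvalue
            )
    return pd.Series(out, name="p_wilcoxon").rename_axis("orf_id")


# ---------------------------------------------------------------------------
# hit classification


def classify_hits(stats: pd.DataFrame, cfg: StatConfig | None = None, cohort: str = "newly_diagnosed") -> pd.DataFrame:
    """Apply the per-cohort hit rule and return the hit table.

    Newly diagnosed: hit = case_exclusive OR fold-change above threshold.
    Pre-diagnostic: hit = OR >= threshold with one-sided p < alpha.
    """
    cfg = cfg or StatConfig()
    if cohort == "newly_diagnosed":
        for col in ("case_exclusive", "fc_gt2"):
            if col not in stats.columns:
                raise ValueError(f"stats table lacks column {col!r} needed for {cohort}")
        hit = stats["case_exclusive"] | stats["fc_gt2"]
    elif cohort == "pre_diagnostic":
        if "or_hit" not in stats.columns:
            raise ValueError("stats table lacks column 'or_hit' needed for pre_diagnostic")
        hit = stats["or_hit"]
    else:
        raise ValueError(f"unknown cohort rule {cohort!r}")
    out = stats.copy()
    out["hit"] = hit
    return out[out["hit"]]


def overlap_report(hit_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Intersections between named hit sets, as counts and id lists."""
    rows = []
    names = list(hit_sets)
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(set(hit_sets[n]) for n in combo))
            rows.append(
                {"sets": "&".join(combo), "count": len(inter), "ids": ";".join(sorted(inter))}
            )
    return pd.DataFrame(rows)


def cohort_statistics(
    qm: QuantMatrix,
    design: Sequence[CohortDesign],
    method: str = "logistic",
    cfg: StatConfig | None = None,
) -> pd.DataFrame:
    """Full per-cryptoprotein stats table: fold-change, OR, Wilcoxon, flags."""
    cfg = cfg or StatConfig()
    fc = fold_change_table(qm, design, cfg)
    orr = odds_ratio(qm, design, method=method, cfg=cfg)
    wil = wilcoxon_pvalues(qm, design)
    return fc.join(orr).join(wil)
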