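"""Agreement evaluation: error metrics, correlation, Wilcoxon, Bland-Altman.

Reference and derived respiratory rates are compared per window and
aggregated two ways: *intra-subject* (per subject, across that subject's
windows) and *inter-subject* (per window, across subjects).  Overall metrics
are the average of the metrics computed on per-subject mean pairs and on
per-window mean pairs.

Differences are oriented derived - reference, so a negative Bland-Altman
bias means the derived method underestimates the reference rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA = 0.05  # two-sided significance level used throughout


@dataclass
class RRSeriesPair:
    """Matched reference / derived RR sequences (breaths/min, >= 0)."""

    reference: np.ndarray
    derived: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        self.derived = np.asarray(self.derived, dtype=np.float64)
        if self.reference.size != self.derived.size:
            raise ValueError("reference and derived must have equal length")
        if self.reference.size < 1:
            raise ValueError("need at least one paired observation")
        if np.any(self.reference < 0) or np.any(self.derived < 0):
            raise ValueError("RR values must be >= 0")

    @property
    def n(self) -> int:
        return self.reference.size

    @property
    def differences(self) -> np.ndarray:
        return self.derived - self.reference


@dataclass
class MetricsReport:
    mae: float
    mape_pct: float
    rmse: float
    rho: float
    rho_p: float
    rho_class: str


@dataclass
class BAResult:
    """Bland-Altman bias and 95 % limits of agreement (bias +/- 1.96 sd)."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def mae(pair: RRSeriesPair) -> float:
    """Mean absolute error, breaths/min."""
    return float(np.mean(np.abs(pair.differences)))


def mape(pair: RRSeriesPair) -> float:
    """Mean absolute percentage error relative to the reference.

    Zero-reference pairs are excluded from the sum (with a logged count);
    an all-zero reference is an error.
    """
    ref, der = pair.reference, pair.derived
    mask = ref > 0
    excluded = int(np.count_nonzero(~mask))
    if excluded == pair.n:
        raise ValueError("MAPE undefined: all reference values are zero")
    if excluded:
        logger.warning("mape: excluded %d zero-reference pairs", excluded)
    return float(100.0 * np.mean(np.abs(der[mask] - ref[mask]) / ref[mask]))


def rmse(pair: RRSeriesPair) -> float:
    """Root mean square error, breaths/min."""
    return float(np.sqrt(np.mean(pair.differences ** 2)))


def classify_rho(rho: float) -> str:
    """Correlation strength bands: |rho| < 0.3 weak, <= 0.7 moderate, else strong."""
    a = abs(rho)
    if a < 0.3:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


def pearson(pair: RRSeriesPair) -> Tuple[float, float, str]:
    """Sample Pearson rho, two-sided p (t-transform, n-2 df), and its band."""
    if pair.n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(pair.reference) == 0 or np.ptp(pair.derived) == 0:
        raise ValueError("correlation undefined for a constant series")
    res = stats.pearsonr(pair.reference, pair.derived)
    rho, p = float(res.statistic), float(res.pvalue)
    return rho, p, classify_rho(rho)


def _signed_rank_stat(d: np.ndarray) -> Tuple[float, np.ndarray]:
    """W+ (sum of mid-ranks of positive differences) and the rank vector."""
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    return float(np.sum(ranks[d > 0])), ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p over all 2^m sign assignments.

    Mid-ranks are half-integers at worst, so doubling makes every rank an
    integer and the null distribution of 2*W+ is built by convolution.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for w in r2:
        shifted = np.zeros_like(counts)
        shifted[w:] = counts[: counts.size - w]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = float(counts[: w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(pair: RRSeriesPair, exact_max_m: int = 15) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on derived - reference.

    Zero differences are dropped; ties share mid-ranks.  The null is exact
    (all 2^m sign assignments) for m <= ``exact_max_m``, and a tie-corrected
    normal approximation with continuity correction otherwise.  Returns
    (W, p) with W the sum of ranks of positive differences; all-zero
    differences give p = 1.0 with a warning.
    """
    d = pair.differences
    d = d[d != 0]
    m = d.size
    if m == 0:
        logger.warning("wilcoxon_signed_rank: all differences zero; p = 1.0")
        return 0.0, 1.0
    if m < 2:
        logger.warning("wilcoxon_signed_rank: only %d nonzero difference", m)
    w_plus, ranks = _signed_rank_stat(d)
    if m <= exact_max_m:
        return w_plus, _exact_signed_rank_p(w_plus, ranks)
    mean = m * (m + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def bland_altman(pair: RRSeriesPair) -> BAResult:
    """Bias (mean of derived - reference), sd (n-1), and bias +/- 1.96 sd.

    Also carries the (mean, difference) scatter pairs for plotting.
    """
    if pair.n < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    d = pair.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BAResult(bias=bias, sd=sd,
                    loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
                    means=(pair.reference + pair.derived) / 2.0, diffs=d)


# ---------------------------------------------------------------------------
# Table aggregation.  The RR table is tidy wide-form: one row per
# (subject, window) with a 'reference' column and one column per method.
# ---------------------------------------------------------------------------

def _method_columns(table: pd.DataFrame) -> List[str]:
    reserved = {"subject", "window", "reference"}
    missing = reserved - set(table.columns)
    if missing:
        raise ValueError(f"RR table missing columns: {sorted(missing)}")
    methods = [c for c in table.columns if c not in reserved]
    if not methods:
        raise ValueError("RR table has no method columns")
    return methods


def _aggregate(table: pd.DataFrame, by: str) -> pd.DataFrame:
    methods = _method_columns(table)
    rows = []
    for key, grp in table.groupby(by, sort=True):
        row: Dict[str, float] = {by: key,
                                 "ref_mean": grp["reference"].mean(),
                                 "ref_sd": grp["reference"].std(ddof=1)}
        for mcol in methods:
            row[f"{mcol}_mean"] = grp[mcol].mean()
            row[f"{mcol}_sd"] = grp[mcol].std(ddof=1)
            if len(grp) >= 2:
                pair = RRSeriesPair(grp["reference"].to_numpy(), grp[mcol].to_numpy())
                row[f"{mcol}_wilcoxon_p"] = wilcoxon_signed_rank(pair)[1]
            else:
                logger.info("aggregate: %s=%r has < 2 windows; Wilcoxon skipped", by, key)
                row[f"{mcol}_wilcoxon_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(by)


def aggregate_intra(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean +/- sd of reference and each method, with Wilcoxon p.

    Tests pair the windows within each subject.
    """
    return _aggregate(table, by="subject")


def aggregate_inter(table: pd.DataFrame) -> pd.DataFrame:
    """Per-window mean +/- sd across subjects, with paired Wilcoxon p."""
    return _aggregate(table, by="window")


def overall_metrics(table: pd.DataFrame) -> Dict[str, MetricsReport]:
    """Two-stage overall metrics per method.

    MAE/MAPE/RMSE/rho are computed once on the per-subject mean pairs and
    once on the per-window mean pairs, then the two are averaged
    element-wise (rho p-values are averaged by the same convention and the
    correlation band re-derived from the averaged rho).  Missing cells
    (an incomplete subject x window grid) are an error listing them.
    """
    methods = _method_columns(table)
    counts = table.groupby(["subject", "window"]).size()
    if table[methods + ["reference"]].isna().any().any():
        bad = table[table[methods + ["reference"]].isna().any(axis=1)]
        raise ValueError("RR table has missing cells at "
                         f"{bad[['subject', 'window']].to_records(index=False).tolist()}")
    if counts.max() > 1:
        raise ValueError("duplicate (subject, window) rows in RR table")

    out: Dict[str, MetricsReport] = {}
    intra = table.groupby("subject")[["reference"] + methods].mean()
    inter = table.groupby("window")[["reference"] + methods].mean()
    for mcol in methods:
        reports = []
        for means in (intra, inter):
            pair = RRSeriesPair(means["reference"].to_numpy(), means[mcol].to_numpy())
            rho, p, _ = pearson(pair)
            reports.append((mae(pair), mape(pair), rmse(pair), rho, p))
        avg = [0.5 * (a + b) for a, b in zip(*reports)]
        out[mcol] = MetricsReport(mae=avg[0], mape_pct=avg[1], rmse=avg[2],
                                  rho=avg[3], rho_p=avg[4],
                                  rho_class=classify_rho(avg[3]))
    return out
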