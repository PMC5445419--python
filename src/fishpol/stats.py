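"""Statistics for anterior/posterior mRNA asymmetry.

Summaries follow the box-and-bar convention of the upstream figures:
the box spans a distribution-free 50% confidence region for the
median, the bars a 99% confidence region, and points beyond the bars
are flagged as outliers.  Both intervals come from order statistics of
the sample via the binomial distribution of signs about the median, so
they are exact and make no distributional assumption.  Conventional
quartile boxes are emitted alongside for comparison, clearly labelled.

Group comparisons use the two-sample t-test (Welch by default; a
paired per-cell variant is available, arguably closer to the per-cell
anterior/posterior design).  The mRNA-protein relationship is the
Pearson correlation of posterior fractions, computed both per cell and
over stream-position group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import STREAM_POSITIONS

__all__ = [
    "CellRecord",
    "BoxSummary",
    "GroupComparison",
    "summarize_box",
    "compare_anterior_posterior",
    "compare_by_stream_position",
    "mrna_protein_correlation",
    "records_to_frame",
]


@dataclass
class CellRecord:
    """Per-cell measurements entering the statistical layer."""

    cell_id: str
    anterior_count: float
    posterior_count: float
    stream_position: str = "single"
    anterior_count_sim: float | None = None
    posterior_count_sim: float | None = None
    protein_posterior_fraction: float | None = None
    eccentricity: float | None = None
    qc_pass: bool = True

    def counts(self, estimator: str = "linear") -> tuple[float, float]:
        if estimator == "linear":
            return self.anterior_count, self.posterior_count
        if estimator == "simulated":
            if self.anterior_count_sim is None or self.posterior_count_sim is None:
                raise ValueError(f"cell {self.cell_id}: no simulated counts recorded")
            return self.anterior_count_sim, self.posterior_count_sim
        raise ValueError(f"unknown estimator {estimator!r}")

    def mrna_posterior_fraction(self, estimator: str = "linear") -> float:
        ant, post = self.counts(estimator)
        total = ant + post
        return post / total if total > 0 else float("nan")


@dataclass
class BoxSummary:
    """Median with order-statistic confidence regions and outliers."""

    n: int
    median: float
    box_lo: float  # 50% confidence region for the median
    box_hi: float
    bar_lo: float  # 99% confidence region for the median
    bar_hi: float
    outliers: np.ndarray  # data points beyond the 99% region
    q1: float  # conventional quartiles, for comparison with standard boxplots
    q3: float


@dataclass
class GroupComparison:
    """Two-group comparison (anterior vs posterior counts)."""

    labels: tuple[str, str]
    n: tuple[int, int]
    summaries: tuple[BoxSummary, BoxSummary]
    t_statistic: float
    p_value: float
    test: str
    group: str = ""
    mean_mrna_posterior_fraction: float = float("nan")


def _median_ci_order_stats(x_sorted: np.ndarray, level: float) -> tuple[float, float]:
    """Distribution-free CI for the median from order statistics.

    Largest l with Binom(n, 1/2) cdf(l-1) <= (1-level)/2 gives the
    interval [x_(l), x_(n+1-l)] with coverage >= level; falls back to
    the sample range when n is too small for an interior interval.
    """
    n = len(x_sorted)
    alpha = (1.0 - level) / 2.0
    l = int(sps.binom.ppf(alpha, n, 0.5))  # cdf(l-1) <= alpha < cdf(l)
    if sps.binom.cdf(l, n, 0.5) <= alpha:
        l += 1
    if l < 1:
        return float(x_sorted[0]), float(x_sorted[-1])
    return float(x_sorted[l - 1]), float(x_sorted[n - l])


def summarize_box(values, levels: tuple[float, float] = (0.50, 0.99)) -> BoxSummary:
    """Median plus 50%/99% order-statistic confidence regions.

    Points outside the wider (99%) region are flagged as outliers.
    Requires n >= 3.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) < 3:
        raise ValueError(f"need at least 3 values, got {len(x)}")
    box = _median_ci_order_stats(x, levels[0])
    bar = _median_ci_order_stats(x, levels[1])
    outliers = x[(x < bar[0]) | (x > bar[1])]
    return BoxSummary(
        n=len(x),
        median=float(np.median(x)),
        box_lo=box[0],
        box_hi=box[1],
        bar_lo=bar[0],
        bar_hi=bar[1],
        outliers=outliers,
        q1=float(np.percentile(x, 25)),
        q3=float(np.percentile(x, 75)),
    )


def _two_sample_t(a: np.ndarray, b: np.ndarray, paired: bool) -> tuple[float, float, str]:
    if paired:
        diff = a - b
        if np.all(diff == diff[0]):
            t = 0.0 if diff[0] == 0 else float("inf") * np.sign(diff[0])
            return float(t), float("nan"), "paired"
        res = sps.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue), "paired"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: zero variance on both sides; p is undefined
        if a[0] == b[0]:
            return 0.0, float("nan"), "welch"
        return float("inf") * np.sign(a[0] - b[0]), float("nan"), "welch"
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), "welch"


def compare_anterior_posterior(
    records: list[CellRecord],
    estimator: str = "linear",
    paired: bool = False,
) -> GroupComparison:
    """Anterior vs posterior unit counts across cells.

    Welch's unpaired t-test by default; ``paired=True`` tests the
    per-cell anterior-posterior differences instead.  The t statistic
    is anterior minus posterior, so posterior enrichment gives t < 0.
    """
    kept = [r for r in records if r.qc_pass]
    if len(kept) < 2:
        raise ValueError("need at least 2 records passing QC")
    ant = np.array([r.counts(estimator)[0] for r in kept], dtype=float)
    post = np.array([r.counts(estimator)[1] for r in kept], dtype=float)
    t, p, test = _two_sample_t(ant, post, paired)
    fracs = [r.mrna_posterior_fraction(estimator) for r in kept]
    return GroupComparison(
        labels=("anterior", "posterior"),
        n=(len(ant), len(post)),
        summaries=(summarize_box(ant), summarize_box(post)),
        t_statistic=t,
        p_value=p,
        test=test,
        mean_mrna_posterior_fraction=float(np.nanmean(fracs)),
    )


def compare_by_stream_position(
    records: list[CellRecord],
    estimator: str = "linear",
    paired: bool = False,
) -> list[GroupComparison]:
    """Per-stream-position anterior/posterior comparisons.

    Groups are ordered beginning, middle, end, single; empty groups
    are skipped with a warning.  Each comparison carries the group's
    mean mRNA posterior fraction.
    """
    present = {r.stream_position for r in records if r.qc_pass}
    out = []
    for pos in STREAM_POSITIONS:
        grp = [r for r in records if r.qc_pass and r.stream_position == pos]
        if not grp:
            if pos in present:  # pragma: no cover - can't happen, defensive
                warnings.warn(f"group {pos!r} empty after QC; skipped", stacklevel=2)
            continue
        if len(grp) < 2:
            warnings.warn(f"group {pos!r} has < 2 cells; skipped", stacklevel=2)
            continue
        cmp = compare_anterior_posterior(grp, estimator=estimator, paired=paired)
        cmp.group = pos
        out.append(cmp)
    if not out:
        raise ValueError("no stream-position group has >= 2 usable cells")
    return out


def mrna_protein_correlation(
    records: list[CellRecord],
    estimator: str = "linear",
    by: str = "cell",
) -> tuple[float, int]:
    """Pearson correlation of mRNA vs protein posterior fractions.

    ``by="cell"`` correlates per-cell fractions; ``by="position"``
    correlates stream-position group means (the variant with one point
    per position).  Returns (r, n points).  Zero variance in either
    vector makes r undefined (returned as nan, with a warning).
    """
    kept = [
        r
        for r in records
        if r.qc_pass and r.protein_posterior_fraction is not None
    ]
    mrna = np.array([r.mrna_posterior_fraction(estimator) for r in kept])
    prot = np.array([r.protein_posterior_fraction for r in kept], dtype=float)
    ok = np.isfinite(mrna) & np.isfinite(prot)
    mrna, prot = mrna[ok], prot[ok]
    if by == "position":
        pos = np.array([r.stream_position for r in kept])[ok]
        groups = [p for p in STREAM_POSITIONS if (pos == p).any()]
        mrna = np.array([mrna[pos == p].mean() for p in groups])
        prot = np.array([prot[pos == p].mean() for p in groups])
    elif by != "cell":
        raise ValueError(f"by must be 'cell' or 'position', got {by!r}")
    n = len(mrna)
    if n < 3:
        raise ValueError(f"need at least 3 paired values, got {n}")
    if np.ptp(mrna) == 0 or np.ptp(prot) == 0:
        warnings.warn("zero variance in one vector; correlation undefined", stacklevel=2)
        return float("nan"), n
    r, _ = sps.pearsonr(mrna, prot)
    return float(r), n


def records_to_frame(records: list[CellRecord], estimator: str = "linear") -> pd.DataFrame:
    """Tidy per-cell table for CSV export."""
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "stream_position": r.stream_position,
                "anterior_count": r.anterior_count,
                "posterior_count": r.posterior_count,
                "anterior_count_sim": r.anterior_count_sim,
                "posterior_count_sim": r.posterior_count_sim,
                "mrna_posterior_fraction": r.mrna_posterior_fraction(estimator)
                if (r.anterior_count + r.posterior_count) > 0
                else np.nan,
                "protein_posterior_fraction": r.protein_posterior_fraction,
                "eccentricity": r.eccentricity,
                "qc_pass": r.qc_pass,
            }
        )
    return pd.DataFrame(rows)
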