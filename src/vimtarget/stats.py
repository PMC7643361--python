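"""Outcome statistics: cohort summary, paired tests, and metric correlations.

CRST A+B is the treated-hand tremor subscore (parts A and B summed), 0-32
points, lower is better.  Improvement is assessed baseline vs 1 month with
a paired t test and a Wilcoxon signed-rank test with continuity correction;
image-derived metrics are related to the 1-month score with Pearson
correlations (no multiplicity adjustment — each metric is reported as-is,
which is a caveat for interpretation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import METRIC_COLUMNS

__all__ = [
    "OutcomeRecord",
    "OutcomeSummary",
    "CorrelationResult",
    "ET_COHORT_CRST",
    "et_cohort_records",
    "load_outcomes_tsv",
    "summarize_outcomes",
    "paired_t",
    "wilcoxon_signed_rank",
    "pearson",
    "correlate_all",
]


@dataclass(frozen=True)
class OutcomeRecord:
    """One patient's CRST A+B scores at baseline and 1 month."""

    patient_id: str
    crst_baseline: int
    crst_1month: int

    def __post_init__(self) -> None:
        for v in (self.crst_baseline, self.crst_1month):
            if not 0 <= v <= 32:
                raise ValueError(f"CRST A+B score {v} outside [0, 32]")


# Printed CRST A+B scores (baseline, 1 month) of the 14-patient MRgFUS
# essential-tremor cohort, patients A-N.  Reference input data.
ET_COHORT_CRST: tuple[tuple[str, int, int], ...] = (
    ("A", 21, 15), ("B", 25, 12), ("C", 11, 4), ("D", 20, 5),
    ("E", 20, 2), ("F", 20, 8), ("G", 21, 5), ("H", 22, 19),
    ("I", 18, 4), ("J", 23, 8), ("K", 22, 7), ("L", 25, 10),
    ("M", 19, 8), ("N", 14, 8),
)


def et_cohort_records() -> list[OutcomeRecord]:
    """The 14 treated-cohort CRST pairs as outcome records."""
    return [OutcomeRecord(p, b, m) for p, b, m in ET_COHORT_CRST]


def load_outcomes_tsv(path: str | Path) -> list[OutcomeRecord]:
    """Read an outcomes TSV (patient_id, [treated_side,] crst_baseline,
    crst_1month)."""
    df = pd.read_csv(path, sep="\t")
    return [
        OutcomeRecord(str(r.patient_id), int(r.crst_baseline), int(r.crst_1month))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class OutcomeSummary:
    mean_baseline: float
    sd_baseline: float
    mean_1month: float
    sd_1month: float


def summarize_outcomes(records: Sequence[OutcomeRecord]) -> OutcomeSummary:
    """Cohort means and sample (n−1) standard deviations of both timepoints."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    base = np.array([r.crst_baseline for r in records], dtype=float)
    month = np.array([r.crst_1month for r in records], dtype=float)
    return OutcomeSummary(
        mean_baseline=float(base.mean()),
        sd_baseline=float(base.std(ddof=1)),
        mean_1month=float(month.mean()),
        sd_1month=float(month.std(ddof=1)),
    )


def paired_t(
    baseline: Sequence[float], followup: Sequence[float]
) -> tuple[float, int, float]:
    """Paired t test on d = baseline − followup.

    Returns (t, df, two-sided p); t = mean(d) / (sd(d)/sqrt(n)), df = n−1.
    A positive t means improvement (scores fell).
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1 or len(b) < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = b - f
    sd = d.std(ddof=1)
    if sd == 0 and d.mean() != 0:
        raise ValueError("zero-variance nonzero differences: t undefined")
    n = len(d)
    if sd == 0:
        return 0.0, n - 1, 1.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def wilcoxon_signed_rank(
    baseline: Sequence[float], followup: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test with continuity correction.

    Zero differences are dropped; absolute differences are ranked with
    midranks for ties.  W is the smaller of the positive/negative signed
    rank sums; the two-sided p uses the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("need two equal-length samples")
    d = b - f
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)

    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        raise ValueError("degenerate rank variance")
    diff = w - mn
    correction = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - correction) / np.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return w, min(p, 1.0)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided p from the t transform (n−2 df)."""

    r: float
    p_two_sided: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with two-sided p.

    p comes from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r, 0.0, n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n)


def correlate_all(
    rows: pd.DataFrame, metric_columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation of every metric column against the 1-month score.

    ``rows`` is the per-patient metrics table (one row per patient, with a
    ``crst_1month`` column).  Returns a table (metric, r, p_two_sided, n),
    unadjusted for multiple comparisons.
    """
    cols = list(metric_columns) if metric_columns is not None else list(METRIC_COLUMNS)
    if len(rows) < 3:
        raise ValueError("need at least 3 complete rows")
    y = rows["crst_1month"].to_numpy(dtype=float)
    out = []
    for col in cols:
        res = pearson(rows[col].to_numpy(dtype=float), y)
        out.append({"metric": col, "r": res.r, "p_two_sided": res.p_two_sided, "n": res.n})
    return pd.DataFrame(out)
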