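"""Sequence-comparison statistics.

Implements the comparison metrics of the three-sequence design: the
pixel-SD homogeneity rule and its per-sequence proportions, the signed
integer percent difference of a sequence's T2 against the reference
sequence (MESE), the per-sequence summary (mean, between-sample SD,
95% t-interval), and the paired t-test on sample-aligned T2 values.

The study's mixed-effects models and Tukey-type multiplicity
adjustments are deliberately not re-implemented here: the pipeline
exports tidy per-segment/per-sample tables that off-the-shelf
statistical software consumes directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HOMOGENEITY_THRESHOLD",
    "flag_inhomogeneous",
    "inhomogeneity_proportion",
    "percent_difference",
    "PairedTTestResult",
    "paired_t_test",
    "SummaryRow",
    "summary_with_ci",
    "ci_from_moments",
]

#: a segment is inhomogeneous when its pixel SD strictly exceeds this
#: fraction of its mean T2
HOMOGENEITY_THRESHOLD = 0.20


def flag_inhomogeneous(
    stats: pd.DataFrame, threshold_fraction: float = HOMOGENEITY_THRESHOLD
) -> pd.DataFrame:
    """Add an ``inhomogeneous`` column: pixel SD > threshold * mean (strict).

    Expects the ``segment_stats`` column layout (``mean_t2_ms``,
    ``sd_t2_ms``).  Rows with missing SD get a missing flag and are
    excluded from downstream proportions.  Returns a copy.
    """
    out = stats.copy()
    mean = out["mean_t2_ms"].to_numpy(dtype=float)
    sd = out["sd_t2_ms"].to_numpy(dtype=float)
    flag = np.where(np.isnan(sd) | np.isnan(mean), np.nan, sd > threshold_fraction * mean)
    out["inhomogeneous"] = pd.array(
        [bool(f) if not np.isnan(f) else pd.NA for f in flag], dtype="boolean"
    )
    return out


def inhomogeneity_proportion(
    flagged: pd.DataFrame, group_col: str | None = None
) -> float | pd.Series:
    """Share of valid segments flagged inhomogeneous.

    With ``group_col`` (e.g. ``"sequence"``) returns one proportion per
    group; rows with a missing flag are excluded from numerator and
    denominator.
    """
    flags = flagged["inhomogeneous"]
    valid = flags.notna()
    if group_col is None:
        n = int(valid.sum())
        if n == 0:
            raise ValueError("no valid homogeneity flags")
        return float(flags[valid].astype(bool).sum()) / n

    def _prop(s: pd.Series) -> float:
        v = s.notna()
        if not v.any():
            raise ValueError("no valid homogeneity flags in a group")
        return float(s[v].astype(bool).sum()) / int(v.sum())

    return flagged.groupby(group_col)["inhomogeneous"].apply(_prop)


def percent_difference(t2_seq, t2_ref):
    """Signed integer percent difference vs. the reference T2.

    round(100*(t2_seq - t2_ref)/t2_ref), rounding halves away from zero
    (numpy's default rounds halves to even, which does not reproduce
    reported integer percent columns).
    """
    t2_seq = np.asarray(t2_seq, dtype=float)
    t2_ref = np.asarray(t2_ref, dtype=float)
    if np.any(t2_ref <= 0):
        raise ValueError("reference T2 must be > 0")
    pct = 100.0 * (t2_seq - t2_ref) / t2_ref
    rounded = np.sign(pct) * np.floor(np.abs(pct) + 0.5)
    out = rounded.astype(int)
    return int(out) if out.ndim == 0 else out


class PairedTTestResult(NamedTuple):
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_t_test(x, y) -> PairedTTestResult:
    """Two-sided paired t-test: t = mean(d)/(SD(d)/sqrt(n)), d = x - y.

    Zero-variance differences are a degenerate design and are reported
    as such (t is +/-inf with p = 0 for a constant nonzero shift, NaN
    when x == y exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    df = n - 1
    sd = float(np.std(d, ddof=1))
    md = float(np.mean(d))
    if sd == 0.0:
        if md == 0.0:
            return PairedTTestResult(np.nan, df, np.nan, degenerate=True)
        return PairedTTestResult(np.inf * np.sign(md), df, 0.0, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTTestResult(float(t), df, float(p))


@dataclass(frozen=True)
class SummaryRow:
    """Per-sequence summary: mean, between-sample SD, 95% t-interval."""

    sequence: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95

    def rounded(self, ndigits: int = 1) -> "SummaryRow":
        """Reporting precision: 1 decimal, like published T2 tables."""
        return SummaryRow(
            self.sequence,
            round(self.mean, ndigits),
            round(self.sd, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
            self.n,
            self.level,
        )


def ci_from_moments(
    mean: float, sd: float, n: int, level: float = 0.95, sequence: str = ""
) -> SummaryRow:
    """t-interval for the mean from (mean, SD, n):
    mean +/- t_{1-alpha/2, n-1} * SD / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    tq = sps.t.ppf(0.5 + level / 2.0, n - 1)
    half = tq * sd / np.sqrt(n)
    return SummaryRow(sequence, float(mean), float(sd), float(mean - half), float(mean + half), int(n), level)


def summary_with_ci(values, level: float = 0.95, sequence: str = "") -> SummaryRow:
    """Mean, sample SD and 95% t-CI of per-sample T2 means."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D vector with n >= 2")
    return ci_from_moments(
        float(np.mean(values)), float(np.std(values, ddof=1)), values.size, level, sequence
    )
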