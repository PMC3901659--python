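"""Test-retest agreement statistics for repeated tract measurements.

Implements the reliability battery used to validate manual tract
segmentation protocols:

* **within-subject SD** — sqrt of the mean within-subject variance; for two
  repeats per subject the within-subject variance is the mean of
  (difference^2 / 2) over subjects;
* **repeatability coefficient** — 2.77 x within-subject SD; for the same
  subject, the difference between two measurements is expected to fall
  below this bound for 95% of measurement pairs (2.77 approximates
  sqrt(2) x 1.96 and is used exactly as the conventional constant);
* **ICC(1)** — one-way random-effects intraclass correlation from ANOVA
  mean squares, with the exact F-based 95% confidence interval;
* **Dice similarity index** — 2|A∩B| / (|A| + |B|) spatial overlap of two
  voxel-set segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Conventional repeatability multiplier (sqrt(2) * 1.96, rounded).
REPEATABILITY_CONSTANT = 2.77


@dataclass
class PairedMeasurements:
    """Two repeated measurements per subject, in the same units."""

    subject_ids: np.ndarray
    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if not (len(self.subject_ids) == len(self.m1) == len(self.m2)):
            raise ValueError("subject_ids, m1, m2 must have equal length")
        if len(self.m1) == 0:
            raise ValueError("no measurement pairs supplied")
        if not (np.isfinite(self.m1).all() and np.isfinite(self.m2).all()):
            raise ValueError("measurements must be finite")

    def __len__(self) -> int:
        return len(self.m1)


@dataclass
class ReliabilityReport:
    within_subject_sd: float
    repeatability: float
    icc: float
    icc_ci: tuple[float, float]
    dice: float | None = None


def within_subject_sd(pairs: PairedMeasurements) -> float:
    """sqrt( mean over subjects of (m1 - m2)^2 / 2 ).

    Invariant to swapping the two repeats and to adding a constant to both.
    """
    d = pairs.m1 - pairs.m2
    return float(np.sqrt(np.mean(d ** 2 / 2.0)))


def repeatability_coefficient(sw: float) -> float:
    """2.77 times the within-subject SD (95% bound on a repeat difference)."""
    if sw < 0:
        raise ValueError("within-subject SD cannot be negative")
    return REPEATABILITY_CONSTANT * sw


def icc_oneway(measurements: np.ndarray,
               confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """One-way random-effects ICC(1) with its exact F-based interval.

    Parameters
    ----------
    measurements : (n_subjects, k_repeats) array
        Complete balanced table, n >= 2 and k >= 2.

    Returns
    -------
    (icc, (lower, upper))
        ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW) from the one-way ANOVA
        mean squares; the interval inverts the F distribution of MSB/MSW
        with (n-1, n(k-1)) degrees of freedom.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2 subjects) x (k >= 2 repeats) table")
    if not np.isfinite(x).all():
        raise ValueError("measurement table must be complete and finite")
    n, k = x.shape
    grand = x.mean()
    subject_means = x.mean(axis=1)
    ssb = k * ((subject_means - grand) ** 2).sum()
    ssw = ((x - subject_means[:, None]) ** 2).sum()
    scale = max(1.0, abs(grand)) ** 2
    if (ssb + ssw) <= 1e-24 * scale * x.size:
        raise ValueError("zero total variance: ICC undefined")
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0:
        return 1.0, (1.0, 1.0)
    icc = (msb - msw) / (msb + (k - 1) * msw)

    alpha = 1.0 - confidence
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lower = (f_l - 1) / (f_l + k - 1)
    upper = (f_u - 1) / (f_u + k - 1)
    return float(icc), (float(lower), float(upper))


def dice_index(voxels_a, voxels_b) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) of two voxel sets."""
    a, b = set(voxels_a), set(voxels_b)
    if not a and not b:
        raise ValueError("Dice undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def coverage_of_repeatability(sw: float, n_pairs: int, seed: int,
                              multiplier: float = REPEATABILITY_CONSTANT
                              ) -> float:
    """Fraction of simulated repeat pairs within the repeatability bound.

    Each pair's difference is normal with SD sw*sqrt(2) (two independent
    errors of SD sw); returns the fraction with |difference| < multiplier*sw.
    The theoretical value at multiplier 2.77 is ~0.95.
    """
    if sw <= 0:
        raise ValueError("within-subject SD must be positive")
    rng = np.random.default_rng(seed)
    diffs = rng.normal(0.0, sw * np.sqrt(2.0), size=n_pairs)
    return float(np.mean(np.abs(diffs) < multiplier * sw))


def reliability_summary(pairs: PairedMeasurements,
                        voxels_a=None, voxels_b=None) -> ReliabilityReport:
    """Full agreement battery for one metric's paired measurements."""
    sw = within_subject_sd(pairs)
    icc, ci = icc_oneway(np.column_stack([pairs.m1, pairs.m2]))
    dice = None
    if voxels_a is not None and voxels_b is not None:
        dice = dice_index(voxels_a, voxels_b)
    return ReliabilityReport(within_subject_sd=sw,
                             repeatability=repeatability_coefficient(sw),
                             icc=icc, icc_ci=ci, dice=dice)


#: display rounding: one decimal for count-scale SD/repeatability,
#: three decimals for ICC and Dice
def _round_pair(value: float, decimals: int) -> float:
    return float(np.round(value, decimals))


def reliability_table(metrics_df: pd.DataFrame,
                      value_columns=("n_voxels", "n_fibers", "mean_fa"),
                      subject_col: str = "subject",
                      repeat_col: str = "repeat",
                      tract_col: str = "tract") -> pd.DataFrame:
    """Per-tract, per-metric agreement report from a two-repeat metrics table.

    ``metrics_df`` is the stacked metrics CSV: one row per subject x repeat
    x tract with the six metric columns.  Exactly two repeats per subject
    and tract are required.  Output mirrors the reliability tables: mean
    (SD) across subjects' first repeats, within-subject SD, repeatability,
    and ICC with its 95% CI.
    """
    rows = []
    for tract, sub in metrics_df.groupby(tract_col, sort=False):
        wide = {}
        for col in value_columns:
            piv = sub.pivot_table(index=subject_col, columns=repeat_col,
                                  values=col)
            if piv.shape[1] != 2 or piv.isna().any().any():
                raise ValueError(
                    f"tract {tract!r}, metric {col!r}: need exactly two "
                    "complete repeats per subject")
            wide[col] = piv.to_numpy()
        for col, arr in wide.items():
            pairs = PairedMeasurements(
                subject_ids=np.arange(arr.shape[0]),
                m1=arr[:, 0], m2=arr[:, 1])
            sw = within_subject_sd(pairs)
            icc, ci = icc_oneway(arr)
            count_scale = col.startswith("n_")
            dec = 1 if count_scale else 3
            rows.append({
                tract_col: tract, "metric": col,
                "mean": _round_pair(arr[:, 0].mean(), dec),
                "sd": _round_pair(arr[:, 0].std(ddof=1), dec),
                "within_subject_sd": _round_pair(sw, dec),
                "repeatability": _round_pair(
                    repeatability_coefficient(sw), dec),
                "icc": _round_pair(icc, 3),
                "icc_lower": _round_pair(ci[0], 3),
                "icc_upper": _round_pair(ci[1], 3),
            })
    return pd.DataFrame(rows)
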