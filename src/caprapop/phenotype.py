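"""Morphometric descriptive statistics and the heart-girth body-weight model.

Live body weight of an adult goat is predicted from heart girth (HG, the
chest circumference behind the front legs, in cm) by the quadratic
BW = 0.0127 HG^2 - 0.69 HG + 14.7 (kg), which is strictly increasing above
HG ~ 27 cm, so medians and quartiles commute through it on the adult range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BW_A, BW_B, BW_C = 0.0127, -0.69, 14.7

MORPHO_TRAITS = ("WH", "CrH", "ChH", "ChL", "TL", "CrL", "CW", "HB", "CxW", "HG", "SC")


def estimate_bw(hg):
    """Body weight (kg) from heart girth (cm); accepts scalars or arrays."""
    hg_arr = np.asarray(hg, dtype=np.float64)
    if (hg_arr < 0).any():
        raise ValueError("heart girth must be non-negative")
    bw = BW_A * hg_arr**2 + BW_B * hg_arr + BW_C
    return float(bw) if np.isscalar(hg) or hg_arr.ndim == 0 else bw


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    n: int
    mean: float
    q1: float
    median: float
    q3: float
    sd: float
    ci_low: float
    ci_high: float
    skewness: float  # NaN when undefined (zero variance)
    kurtosis: float  # excess kurtosis; NaN when undefined


def describe(table: pd.DataFrame, trait: str, quartile_method: str = "linear") -> TraitSummary:
    """Descriptive summary of one trait column.

    Quartiles use linear interpolation by default (``quartile_method`` is any
    numpy quantile method, e.g. ``"averaged_inverted_cdf"`` for the SAS-style
    definition).  Skewness and kurtosis are the sample-adjusted (bias
    corrected) moments, kurtosis reported as excess; the CI is the
    t-based 95% interval of the mean.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    x = pd.to_numeric(table[trait], errors="coerce").dropna().to_numpy(dtype=np.float64)
    n = x.size
    if n < 3:
        raise ValueError(f"trait {trait!r}: need >= 3 non-missing values, have {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    q1, med, q3 = (float(np.quantile(x, q, method=quartile_method)) for q in (0.25, 0.5, 0.75))
    tcrit = stats.t.ppf(0.975, n - 1)
    half = tcrit * sd / np.sqrt(n)
    if sd == 0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return TraitSummary(
        trait=trait, n=n, mean=mean, q1=q1, median=med, q3=q3, sd=sd,
        ci_low=mean - half, ci_high=mean + half, skewness=skew, kurtosis=kurt,
    )


def read_morphometrics(path) -> pd.DataFrame:
    """Morphometrics CSV: sample_id plus per-trait measurement columns (cm)."""
    table = pd.read_csv(path)
    if "sample_id" not in table.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return table


def summary_table(table: pd.DataFrame, traits=None, **kwargs) -> pd.DataFrame:
    """Stacked :func:`describe` rows for the given traits (default: all present)."""
    if traits is None:
        traits = [t for t in MORPHO_TRAITS if t in table.columns]
        if "BW" in table.columns:
            traits = ["BW"] + traits
    rows = [describe(table, t, **kwargs).__dict__ for t in traits]
    return pd.DataFrame(rows)
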