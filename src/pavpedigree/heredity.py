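"""Hereditary stability and the pedigree-to-population bottleneck effect.

Hereditary stability of a reference segment is the number of progenies
that retain it; the bottleneck contrast asks whether segments poorly
retained within the pedigree (parents included) also sit at depressed
presence frequencies in the broad population.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CATEGORIES, PresenceMatrix


def retention_counts(matrix: PresenceMatrix) -> pd.DataFrame:
    """Per-segment retention among progenies, pedigree carrier count
    (parents + progenies), and population presence frequency.

    MISSING entries count neither toward carriers nor the frequency
    denominator.
    """
    prog = matrix.data[matrix.progeny_samples]
    ped = matrix.data[matrix.pedigree_samples]
    out = pd.DataFrame(index=matrix.segment_ids.copy())
    out["retention"] = (prog == 1.0).sum(axis=1).astype(int)
    out["pedigree_carriers"] = (ped == 1.0).sum(axis=1).astype(int)
    pop_cols = matrix.population_samples
    if pop_cols:
        pop = matrix.data[pop_cols]
        genotyped = pop.notna().sum(axis=1)
        with np.errstate(invalid="ignore"):
            out["pop_freq"] = ((pop == 1.0).sum(axis=1) / genotyped).astype(float)
    else:
        out["pop_freq"] = np.nan
    out.index.name = "segment_id"
    return out


def stability_compare(
    records: pd.DataFrame,
    categories: pd.Series,
    segment_filter: Optional[Sequence[str]] = None,
    value: str = "retention",
) -> pd.DataFrame:
    """Pairwise Welch t-tests of retention between source categories.

    Returns one row per unordered category pair with group means, the
    lower-mean side, and the two-sided P; pairs with an empty or
    singleton side are reported with NaN statistics.
    """
    df = records.join(categories.rename("category"))
    if segment_filter is not None:
        df = df.loc[df.index.intersection(segment_filter)]
    rows = []
    for a, b in combinations(CATEGORIES, 2):
        xa = df.loc[df["category"] == a, value].to_numpy(float)
        xb = df.loc[df["category"] == b, value].to_numpy(float)
        if len(xa) < 2 or len(xb) < 2:
            rows.append((a, b, xa.mean() if len(xa) else np.nan,
                         xb.mean() if len(xb) else np.nan, None, np.nan))
            continue
        _, p = stats.ttest_ind(xa, xb, equal_var=False)
        lower = a if xa.mean() < xb.mean() else b
        rows.append((a, b, float(xa.mean()), float(xb.mean()), lower, float(p)))
    return pd.DataFrame(
        rows, columns=["category_a", "category_b", "mean_a", "mean_b",
                       "lower_mean", "p_value"]
    )


@dataclass
class BottleneckResult:
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    t: float
    p_value: float
    low_thresh: int
    high_thresh: int


def bottleneck_test(
    records: pd.DataFrame, low_thresh: int = 6, high_thresh: int = 12
) -> BottleneckResult:
    """Welch t-test of population presence frequency between segments
    retained by fewer than ``low_thresh`` pedigree members and those
    retained by more than ``high_thresh``."""
    if low_thresh >= high_thresh:
        raise ValueError("low_thresh must be below high_thresh")
    lo = records.loc[records["pedigree_carriers"] < low_thresh, "pop_freq"].dropna()
    hi = records.loc[records["pedigree_carriers"] > high_thresh, "pop_freq"].dropna()
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("empty contrast group")
    t, p = stats.ttest_ind(lo, hi, equal_var=False)
    return BottleneckResult(
        n_low=len(lo),
        n_high=len(hi),
        mean_low=float(lo.mean()),
        mean_high=float(hi.mean()),
        t=float(t),
        p_value=float(p),
        low_thresh=low_thresh,
        high_thresh=high_thresh,
    )
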