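"""Segment source categories and per-trait effect orientation.

The source category of a reference segment is a pure function of the two
parents' allele states; the effect orientation compares the trait between
carriers of the reference segment and carriers of the variation, on a
polarity-oriented scale so that FAVORABLE always means "losing the
reference segment worsens the trait".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ALT,
    BIPARENTAL,
    CATEGORIES,
    DELETERIOUS,
    FAVORABLE,
    MISSING,
    NONE,
    P1_INHERITED,
    P2_INHERITED,
    REF,
    REF_SPECIFIC,
    UNCLASSIFIED,
)


@dataclass(frozen=True)
class TraitPolarity:
    trait: str
    higher_is_better: bool


_SOURCE_TABLE = {
    (REF, ALT): P1_INHERITED,
    (ALT, REF): P2_INHERITED,
    (ALT, ALT): REF_SPECIFIC,
    (REF, REF): BIPARENTAL,
}


def classify_source(p1_allele: str, p2_allele: str) -> str:
    """Category from the two parents' allele states.

    Parent#1 carrying the reference segment while Parent#2 carries the
    variation means the reference inherited it from Parent#1, and so on;
    both parents carrying the variation marks a reference-specific segment,
    both carrying the reference segment a biparental one. Any MISSING
    parent leaves the segment UNCLASSIFIED.
    """
    for a in (p1_allele, p2_allele):
        if a not in (REF, ALT, MISSING):
            raise ValueError(f"invalid allele state {a!r}")
    if MISSING in (p1_allele, p2_allele):
        return UNCLASSIFIED
    return _SOURCE_TABLE[(p1_allele, p2_allele)]


def classify_sources(matrix, parent1: Optional[str] = None, parent2: Optional[str] = None) -> pd.Series:
    """Vectorized classify_source over a PresenceMatrix."""
    from .core import ROLE_PARENT1, ROLE_PARENT2

    p1 = parent1 or matrix.samples_with_role(ROLE_PARENT1)[0]
    p2 = parent2 or matrix.samples_with_role(ROLE_PARENT2)[0]
    a1 = matrix.data[p1].to_numpy()
    a2 = matrix.data[p2].to_numpy()
    out = np.full(len(a1), UNCLASSIFIED, dtype=object)
    known = ~np.isnan(a1) & ~np.isnan(a2)
    out[known & (a1 == 1) & (a2 == 0)] = P1_INHERITED
    out[known & (a1 == 0) & (a2 == 1)] = P2_INHERITED
    out[known & (a1 == 0) & (a2 == 0)] = REF_SPECIFIC
    out[known & (a1 == 1) & (a2 == 1)] = BIPARENTAL
    return pd.Series(out, index=matrix.segment_ids, name="category")


@dataclass
class EffectResult:
    effect: str
    p_value: float
    mean_ref: float  # raw trait mean among reference-segment carriers
    mean_alt: float
    n_ref: int
    n_alt: int


def classify_effect(
    presence: pd.Series,
    trait: pd.Series,
    polarity: TraitPolarity,
    alpha_divergence: float = 0.05,
) -> EffectResult:
    """Favorable/deleterious orientation of one segment for one trait.

    Welch's two-sided t-test between reference-segment carriers and
    variation carriers on the improvement-oriented trait u (= trait when
    higher is better, else -trait). Significant divergence with carriers
    of the variation doing worse marks the reference segment FAVORABLE.
    """
    common = presence.index.intersection(trait.dropna().index)
    g = presence.loc[common]
    y = trait.loc[common]
    mask = g.notna()
    g, y = g[mask], y[mask]
    u = y if polarity.higher_is_better else -y
    u_ref, u_alt = u[g == 1.0], u[g == 0.0]
    n_ref, n_alt = len(u_ref), len(u_alt)
    mean_ref = float(y[g == 1.0].mean()) if n_ref else np.nan
    mean_alt = float(y[g == 0.0].mean()) if n_alt else np.nan
    if n_ref < 2 or n_alt < 2:
        warnings.warn(
            f"genotype group of size < 2 for trait {polarity.trait!r}; effect NONE",
            stacklevel=2,
        )
        return EffectResult(NONE, np.nan, mean_ref, mean_alt, n_ref, n_alt)
    t, p = stats.ttest_ind(u_ref, u_alt, equal_var=False)
    p = float(p)
    if np.isnan(p) or p > alpha_divergence or u_alt.mean() == u_ref.mean():
        return EffectResult(NONE, p, mean_ref, mean_alt, n_ref, n_alt)
    effect = FAVORABLE if u_alt.mean() < u_ref.mean() else DELETERIOUS
    return EffectResult(effect, p, mean_ref, mean_alt, n_ref, n_alt)


def classify_effects(
    matrix,
    phenotypes: pd.DataFrame,
    polarities: Dict[str, bool],
    alpha_divergence: float = 0.05,
    samples: Optional[list] = None,
) -> pd.DataFrame:
    """classify_effect over all segments and traits; long-form result."""
    cols = samples if samples is not None else list(matrix.data.columns)
    rows = []
    for trait in phenotypes.columns:
        if trait not in polarities:
            raise ValueError(f"unknown trait polarity for {trait!r}")
        pol = TraitPolarity(trait, polarities[trait])
        tr = phenotypes.loc[[s for s in cols if s in phenotypes.index], trait]
        for seg_id, presence in matrix.data[cols].iterrows():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = classify_effect(presence, tr, pol, alpha_divergence)
            rows.append(
                (seg_id, trait, res.effect, res.p_value, res.mean_ref,
                 res.mean_alt, res.n_ref, res.n_alt)
            )
    return pd.DataFrame(
        rows,
        columns=["segment_id", "trait", "effect", "p_divergence",
                 "mean_ref", "mean_alt", "n_ref", "n_alt"],
    )


def category_effect_table(
    annotations: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Favorable/deleterious counts per category per trait.

    ``annotations`` needs columns segment_id, category, trait, effect.
    The favorable fraction is favorable/(favorable+deleterious) as a
    percentage rounded to one decimal (NA when the denominator is 0);
    a chi-square test of category x effect independence is attached
    per trait (NaN when the contingency table is degenerate).
    """
    ann = annotations[annotations["effect"].isin([FAVORABLE, DELETERIOUS])]
    rows = []
    chi_rows = []
    for trait, grp in ann.groupby("trait"):
        for cat in CATEGORIES:
            sub = grp[grp["category"] == cat]
            n_fav = int((sub["effect"] == FAVORABLE).sum())
            n_del = int((sub["effect"] == DELETERIOUS).sum())
            total = n_fav + n_del
            pct = round(100.0 * n_fav / total, 1) if total else np.nan
            rows.append((trait, cat, n_fav, n_del, total, pct))
        ct = pd.crosstab(grp["category"], grp["effect"])
        if ct.shape[0] >= 2 and ct.shape[1] >= 2:
            chi2, p, dof, _ = stats.chi2_contingency(ct)
            chi_rows.append((trait, float(chi2), float(p), int(dof)))
        else:
            chi_rows.append((trait, np.nan, np.nan, 0))
    table = pd.DataFrame(
        rows,
        columns=["trait", "category", "n_favorable", "n_deleterious",
                 "n_total", "favorable_pct"],
    )
    chi = pd.DataFrame(chi_rows, columns=["trait", "chi2", "p_value", "dof"])
    return table, chi
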