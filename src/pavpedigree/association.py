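"""PAV-GWAS filter cascade: association scan, eQTL scan, functional pool,
SV-gene-phenotype (SGP) triplets, and allelic pairs.

The association model is an ordinary linear scan with principal-component
covariates of the centered presence matrix (trait ~ presence + PCs);
thresholds are raw P values (marker P <= 0.01 and phenotype-divergence
P <= 0.05 by default), deliberately without multiple-testing correction,
because the marker set is small. A kinship mixed-model backend is an
extension point, not implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEL, INS, GeneModels, PavRecord, PresenceMatrix
from .pavmap import INS_MAX_DIST


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def presence_pcs(data: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top principal components (sample scores) of the centered presence
    matrix. NaNs are column-mean imputed for the decomposition only."""
    if n_pcs == 0:
        return np.empty((data.shape[0], 0))
    X = data.copy()
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)
    # full SVD on the smaller side for determinism
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :n_pcs] * s[:n_pcs]


def _ols_presence_test(
    g: np.ndarray, y: np.ndarray, C: np.ndarray,
    Q: Optional[np.ndarray] = None, ry: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Slope and two-sided P for y ~ g + C (C includes the intercept),
    via Frisch-Waugh residualization. ``Q``/``ry`` may be precomputed."""
    if Q is None:
        Q, _ = np.linalg.qr(C)
    if ry is None:
        ry = y - Q @ (Q.T @ y)
    rg = g - Q @ (Q.T @ g)
    rgg = float(rg @ rg)
    if rgg < 1e-12:
        return np.nan, np.nan
    slope = float(rg @ ry) / rgg
    resid = ry - slope * rg
    df = len(y) - C.shape[1] - 1
    if df <= 0:
        return slope, np.nan
    s2 = float(resid @ resid) / df
    if s2 <= 0:
        return slope, 0.0
    t = slope / np.sqrt(s2 / rgg)
    return slope, float(2.0 * stats.t.sf(abs(t), df))


def _welch_groups(g: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, int, int]:
    """(p, mean_ref, mean_alt, n_ref, n_alt) for the REF-vs-ALT t-test."""
    y_ref, y_alt = y[g == 1.0], y[g == 0.0]
    n_ref, n_alt = len(y_ref), len(y_alt)
    if n_ref < 2 or n_alt < 2:
        return np.nan, np.nan, np.nan, n_ref, n_alt
    _, p = stats.ttest_ind(y_ref, y_alt, equal_var=False)
    return float(p), float(y_ref.mean()), float(y_alt.mean()), n_ref, n_alt


# --------------------------------------------------------------------------
# association scan
# --------------------------------------------------------------------------

def assoc_scan(
    matrix: PresenceMatrix,
    trait: pd.Series,
    n_pcs: int = 2,
    min_minor: int = 5,
    max_missing: float = 0.2,
    samples: Optional[Sequence[str]] = None,
    min_samples: int = 20,
) -> pd.DataFrame:
    """Per-segment linear association of the trait with segment presence.

    Returns one row per segment: slope (sign of the presence coefficient),
    P_assoc from the covariate-adjusted linear model, P_divergence from
    the Welch t-test between the two genotype groups, group means and
    sizes, and a skip reason for segments not fitted (constant presence,
    minor group below ``min_minor``, or missingness above ``max_missing``).
    """
    cols = list(samples) if samples is not None else list(matrix.data.columns)
    cols = [s for s in cols if s in trait.index and not np.isnan(trait[s])]
    if len(cols) < min_samples:
        raise ValueError(f"need at least {min_samples} phenotyped samples")
    G = matrix.data[cols].to_numpy()  # segments x n
    y = trait.loc[cols].to_numpy(float)
    n = len(cols)
    pcs = presence_pcs(G.T, n_pcs)
    C_full = np.column_stack([np.ones(n), pcs])
    Q_full, _ = np.linalg.qr(C_full)
    ry_full = y - Q_full @ (Q_full.T @ y)
    y_constant = np.std(y) == 0

    rows = []
    for i, seg_id in enumerate(matrix.segment_ids):
        g = G[i]
        miss = np.isnan(g)
        if miss.mean() > max_missing:
            rows.append((seg_id, np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0,
                         "missingness"))
            continue
        keep = ~miss
        gk, yk, Ck = g[keep], y[keep], C_full[keep]
        n_alt = int((gk == 0.0).sum())
        n_ref = int((gk == 1.0).sum())
        if min(n_ref, n_alt) == 0:
            rows.append((seg_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                         n_ref, n_alt, "constant"))
            continue
        if min(n_ref, n_alt) < min_minor:
            rows.append((seg_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                         n_ref, n_alt, "minor_group"))
            continue
        if y_constant:
            p_div, m_ref, m_alt, n_ref, n_alt = _welch_groups(gk, yk)
            rows.append((seg_id, 0.0, 1.0, 1.0, m_ref, m_alt, n_ref, n_alt, ""))
            continue
        if keep.all():
            slope, p = _ols_presence_test(gk, yk, C_full, Q=Q_full, ry=ry_full)
        else:
            slope, p = _ols_presence_test(gk, yk, Ck)
        p_div, m_ref, m_alt, n_ref, n_alt = _welch_groups(gk, yk)
        rows.append((seg_id, slope, p, p_div, m_ref, m_alt, n_ref, n_alt, ""))
    return pd.DataFrame(
        rows,
        columns=["segment_id", "slope", "p_assoc", "p_divergence",
                 "mean_ref", "mean_alt", "n_ref", "n_alt", "skipped"],
    )


def permutation_p(
    g: np.ndarray, y: np.ndarray, n_perm: Optional[int] = None, seed: int = 0
) -> float:
    """Two-sided permutation P for the group mean difference.

    Exhaustive over all labelings when the count of distinct arrangements
    is small (or ``n_perm`` is None and feasible), else Monte Carlo. This
    is the independent oracle the linear scan is validated against.
    """
    g = np.asarray(g, float)
    y = np.asarray(y, float)
    n = len(g)
    k = int((g == 1.0).sum())
    obs = abs(y[g == 1.0].mean() - y[g == 0.0].mean())
    from math import comb

    total = comb(n, k)
    if n_perm is None and total <= 200_000:
        count = 0
        idx = np.arange(n)
        for ref_set in itertools.combinations(idx, k):
            mask = np.zeros(n, bool)
            mask[list(ref_set)] = True
            d = abs(y[mask].mean() - y[~mask].mean())
            if d >= obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    n_perm = n_perm or 10_000
    count = 1
    for _ in range(n_perm):
        mask = np.zeros(n, bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        d = abs(y[mask].mean() - y[~mask].mean())
        if d >= obs - 1e-12:
            count += 1
    return count / (n_perm + 1)


# --------------------------------------------------------------------------
# eQTL scan
# --------------------------------------------------------------------------

def eqtl_scan(
    matrix: PresenceMatrix,
    expression: pd.DataFrame,
    gene_models: Optional[GeneModels] = None,
    records: Optional[Sequence[PavRecord]] = None,
    cis_window: int = 1_000_000,
    screen_alpha: Optional[float] = None,
    n_pcs: int = 2,
    max_missing: float = 0.2,
    min_minor: int = 5,
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Segment x gene linear scan on log2(TPM+1) expression.

    Every pair is tested with the same covariate-adjusted linear contract
    as :func:`assoc_scan`; reported links are the cis pairs (segment within
    ``cis_window`` of the gene extent) plus trans pairs surviving a
    genome-wide screen (default Bonferroni: 0.05 / n_pairs). Genes absent
    from the models are trans by convention.
    """
    cols = list(samples) if samples is not None else list(matrix.data.columns)
    cols = [s for s in cols if s in expression.columns]
    G = matrix.data[cols].to_numpy()
    Y = np.log2(expression[cols].to_numpy(float) + 1.0)  # genes x n
    n = len(cols)
    seg_ids = list(matrix.segment_ids)
    gene_ids = list(expression.index)
    pcs = presence_pcs(G.T, n_pcs)
    C = np.column_stack([np.ones(n), pcs])
    Q, _ = np.linalg.qr(C)

    # testable segments: no missing handling beyond exclusion here
    miss_frac = np.isnan(G).mean(axis=1)
    n_alt = (G == 0.0).sum(axis=1)
    n_ref = (G == 1.0).sum(axis=1)
    testable = (miss_frac <= max_missing) & (np.minimum(n_ref, n_alt) >= min_minor)
    # mean-impute residual missingness (<= max_missing) for the matrix scan
    Gi = G.copy()
    row_mean = np.where(np.isnan(np.nanmean(Gi, axis=1)), 0.0, np.nanmean(Gi, axis=1))
    rr, cc = np.where(np.isnan(Gi))
    Gi[rr, cc] = row_mean[rr]

    RG = Gi - (Gi @ Q) @ Q.T  # segments x n, residualized
    RY = Y - (Y @ Q) @ Q.T    # genes x n
    rgg = (RG * RG).sum(axis=1)
    ryy = (RY * RY).sum(axis=1)
    S = RG @ RY.T  # segments x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = S / rgg[:, None]
        df = n - C.shape[1] - 1
        sse = ryy[None, :] - slope * S
        sse = np.maximum(sse, 0.0)
        se = np.sqrt(sse / df / rgg[:, None])
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p[~testable, :] = np.nan

    cis = np.zeros((len(seg_ids), len(gene_ids)), bool)
    if gene_models is not None and records is not None:
        rec_by_id = {r.id: r for r in records}
        seg_chrom = np.array(
            [rec_by_id[s].chrom if s in rec_by_id else "" for s in seg_ids], object
        )
        seg_pos = np.array([rec_by_id[s].pos if s in rec_by_id else -1 for s in seg_ids])
        seg_end = np.array([rec_by_id[s].end if s in rec_by_id else -1 for s in seg_ids])
        gpos = gene_models.genes.set_index("gene_id")
        for j, gid in enumerate(gene_ids):
            if gid not in gpos.index:
                continue  # gene absent from models: trans by convention
            grow = gpos.loc[gid]
            mask = (
                (seg_chrom == grow["chrom"])
                & (seg_pos <= grow["end"] + cis_window)
                & (seg_end >= grow["start"] - cis_window)
            )
            cis[mask, j] = True

    n_pairs = int(testable.sum()) * len(gene_ids)
    if screen_alpha is None:
        screen_alpha = 0.05 / max(n_pairs, 1)
    keep = cis | (p <= screen_alpha)
    keep &= ~np.isnan(p)
    ii, jj = np.where(keep)
    return pd.DataFrame(
        {
            "segment_id": [seg_ids[i] for i in ii],
            "gene_id": [gene_ids[j] for j in jj],
            "slope": slope[ii, jj],
            "p": p[ii, jj],
            "cis": cis[ii, jj],
        }
    )


# --------------------------------------------------------------------------
# functional pool / SGP triplets / allelic pairs
# --------------------------------------------------------------------------

GENIC_CONTEXTS = ("exon", "intron", "promoter")


def build_functional_pool(
    assoc: pd.DataFrame,
    eqtl: pd.DataFrame,
    contexts: pd.Series,
    alpha_marker: float = 0.01,
    alpha_divergence: float = 0.05,
    eqtl_alpha: float = 1e-3,
) -> pd.DataFrame:
    """Keep segment-trait pairs passing the full filter cascade:
    P_assoc <= alpha_marker, P_divergence <= alpha_divergence, and either
    a genic/promoter context or at least one expression link at
    ``eqtl_alpha``. ``assoc`` may cover several traits (column ``trait``)."""
    assoc = assoc.copy()
    if "trait" not in assoc.columns:
        assoc["trait"] = "trait"
    linked = set(eqtl.loc[eqtl["p"] <= eqtl_alpha, "segment_id"]) if len(eqtl) else set()
    ctx = contexts.reindex(assoc["segment_id"]).to_numpy()
    has_ctx = pd.Series(ctx).isin(GENIC_CONTEXTS).to_numpy()
    has_link = assoc["segment_id"].isin(linked).to_numpy()
    ok = (
        (assoc["p_assoc"] <= alpha_marker).to_numpy()
        & (assoc["p_divergence"] <= alpha_divergence).to_numpy()
        & (has_ctx | has_link)
    )
    pool = assoc[ok].copy()
    pool["has_link"] = has_link[ok]
    pool["context"] = ctx[ok]
    return pool.reset_index(drop=True)


def build_sgp_triplets(
    pool: pd.DataFrame,
    eqtl: pd.DataFrame,
    effects: pd.DataFrame,
    eqtl_alpha: float = 1e-3,
) -> pd.DataFrame:
    """Label (segment, gene, trait) triplets CONSISTENT or CONFLICT.

    s_trait = +1 when carrying the reference segment improves the
    polarity-oriented trait (FAVORABLE), else -1; s_expr is the sign of
    the expression slope on presence. CONSISTENT iff their product is
    positive; zero slopes drop the triplet.
    """
    eff = effects.set_index(["segment_id", "trait"])["effect"]
    links = eqtl[eqtl["p"] <= eqtl_alpha]
    rows = []
    for _, prow in pool.iterrows():
        seg, trait = prow["segment_id"], prow["trait"]
        label_eff = eff.get((seg, trait))
        if label_eff not in ("FAVORABLE", "DELETERIOUS"):
            continue
        s_trait = 1 if label_eff == "FAVORABLE" else -1
        for _, lrow in links[links["segment_id"] == seg].iterrows():
            if lrow["slope"] == 0:
                continue
            s_expr = 1 if lrow["slope"] > 0 else -1
            label = "CONSISTENT" if s_trait * s_expr > 0 else "CONFLICT"
            rows.append((seg, lrow["gene_id"], trait, label))
    return pd.DataFrame(rows, columns=["segment_id", "gene_id", "trait", "label"])


def pair_allelic(
    records: Sequence[PavRecord],
    matrix: Optional[PresenceMatrix] = None,
    trait: Optional[pd.Series] = None,
    ins_max_dist: int = INS_MAX_DIST,
) -> pd.DataFrame:
    """Allelic pairs: distinct records sharing a reference locus.

    After non-redundant merging, two records that still overlap on the
    reference represent distinct alternative alleles at the same locus
    (different SV type, or same type with lengths too different to merge).
    All unordered overlapping pairs are reported; when a matrix and trait
    are given, mean phenotypes of the three genotype classes (A-like,
    B-like, reference-like) are attached.
    """
    by_chrom: Dict[str, List[PavRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for chrom, recs in sorted(by_chrom.items()):
        recs = sorted(recs, key=lambda r: (r.pos, r.end, r.id))
        for i, a in enumerate(recs):
            a_lo = a.pos - (ins_max_dist if a.svtype == INS else 0)
            a_hi = a.end + (ins_max_dist if a.svtype == INS else 0)
            for b in recs[i + 1:]:
                b_lo = b.pos - (ins_max_dist if b.svtype == INS else 0)
                if b_lo > a_hi:
                    break
                b_hi = b.end + (ins_max_dist if b.svtype == INS else 0)
                if min(a_hi, b_hi) - max(a_lo, b_lo) < 0:
                    continue
                row = {
                    "segment_a": a.id,
                    "segment_b": b.id,
                    "chrom": chrom,
                    "locus_start": int(min(a.pos, b.pos)),
                    "locus_end": int(max(a.end, b.end)),
                }
                if matrix is not None and trait is not None:
                    ga = matrix.data.loc[a.id]
                    gb = matrix.data.loc[b.id]
                    common = trait.dropna().index.intersection(ga.index)
                    ga, gb, y = ga[common], gb[common], trait[common]
                    a_like = y[(ga == 0.0) & (gb == 1.0)]
                    b_like = y[(ga == 1.0) & (gb == 0.0)]
                    ref_like = y[(ga == 1.0) & (gb == 1.0)]
                    row.update(
                        mean_a_like=float(a_like.mean()) if len(a_like) else np.nan,
                        mean_b_like=float(b_like.mean()) if len(b_like) else np.nan,
                        mean_ref_like=float(ref_like.mean()) if len(ref_like) else np.nan,
                        n_a_like=len(a_like),
                        n_b_like=len(b_like),
                        n_ref_like=len(ref_like),
                    )
                rows.append(row)
    return pd.DataFrame(rows)
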