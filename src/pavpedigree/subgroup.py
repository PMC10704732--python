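"""NMF sub-grouping of segments and cultivars.

The binary segment-retain matrix S (m segments x n cultivars, 1 = the
cultivar has the segment) is factorized as S ~ W H with W (m x f) the
feature-marker matrix and H (f x n) the feature-sample matrix. The
feature number f is selected by the silhouette of a k-means clustering of
the rows of W; segments and samples are assigned to the sub-group of
their argmax feature, with the maximal value as their score.

The factorization is plain multiplicative-update NMF minimizing the
Frobenius reconstruction error, seeded and with a recorded objective
trace (asserted non-increasing on every run).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

_EPS = 1e-12


def nmf_factorize(
    S: np.ndarray,
    f: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF of a non-negative matrix.

    Returns (W, H, objective_trace) where the trace holds the Frobenius
    reconstruction error after each update; iteration stops when the
    relative objective change drops below ``tol`` or at ``max_iter``.
    Initialization is seeded uniform noise scaled to the matrix mean.
    """
    S = np.asarray(S, float)
    if (S < 0).any():
        raise ValueError("S must be non-negative")
    m, n = S.shape
    if not 2 <= f <= min(m, n):
        raise ValueError(f"feature number {f} out of range [2, {min(m, n)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(S.mean(), _EPS) / f)
    W = rng.uniform(0.0, 1.0, size=(m, f)) * scale
    H = rng.uniform(0.0, 1.0, size=(f, n)) * scale
    trace = [float(np.linalg.norm(S - W @ H))]
    for _ in range(max_iter):
        H *= (W.T @ S) / (W.T @ W @ H + _EPS)
        W *= (S @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(S - W @ H))
        prev = trace[-1]
        trace.append(obj)
        if obj > prev + 1e-8 * max(prev, 1.0):
            raise RuntimeError("NMF objective increased; update rule violated")
        if prev > 0 and (prev - obj) / prev < tol:
            break
    return W, H, np.asarray(trace)


def select_feature_number(
    S: np.ndarray,
    f_range: Iterable[int] = range(2, 11),
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    weak_threshold: float = 0.6,
) -> Tuple[int, pd.Series, bool]:
    """Pick the feature number by silhouette of k-means on the rows of W.

    For each candidate f the matrix is factorized, the rows of W are
    clustered with k-means (k = f, seeded), and the silhouette score is
    recorded; f* is the argmax (ties go to the smaller f). When every
    silhouette stays below ``weak_threshold`` the result is flagged as
    weak structure; the 0.6 default sits between the ~0.5 plateau that
    two-cluster k-means reaches on unstructured matrices and the >= 0.85
    scores of genuinely blocked ones.
    """
    S = np.asarray(S, float)
    m = S.shape[0]
    scores = {}
    for f in f_range:
        if f >= m or f > min(S.shape):
            continue
        W, _, _ = nmf_factorize(S, f, seed=seed, max_iter=max_iter, tol=tol)
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # duplicate W rows can collapse clusters; handled below
            warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(n_clusters=f, n_init=10, random_state=seed).fit(W)
        if len(np.unique(km.labels_)) < 2:
            scores[f] = -1.0
            continue
        scores[f] = float(silhouette_score(W, km.labels_))
    if not scores:
        raise ValueError("no admissible feature number in range")
    series = pd.Series(scores).sort_index()
    f_star = int(series.idxmax())  # idxmax takes the first (smallest) maximizer
    weak = bool(series.max() < weak_threshold)
    if weak:
        logger.warning("weak sub-group structure: max silhouette %.3f", series.max())
    return f_star, series, weak


def assign_subgroups(
    W: np.ndarray,
    H: np.ndarray,
    segment_ids: Sequence[str],
    sample_ids: Sequence[str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Argmax sub-group assignment with feature scores.

    Segments follow the rows of W, samples the columns of H; sub-groups
    are numbered from 1 in feature order, ties resolve to the lowest
    feature index (and are logged).
    """
    W = np.asarray(W, float)
    H = np.asarray(H, float)
    seg_sub = W.argmax(axis=1)
    ties = (W == W.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("%d segment rows had tied feature scores; lowest index used",
                    int(ties.sum()))
    segments = pd.DataFrame(
        {
            "segment_id": list(segment_ids),
            "subgroup": seg_sub + 1,
            "score": W.max(axis=1),
        }
    )
    smp_sub = H.argmax(axis=0)
    sties = (H == H.max(axis=0, keepdims=True)).sum(axis=0) > 1
    if sties.any():
        logger.info("%d sample columns had tied feature scores; lowest index used",
                    int(sties.sum()))
    samples = pd.DataFrame(
        {
            "sample": list(sample_ids),
            "subgroup": smp_sub + 1,
            "score": H.max(axis=0),
        }
    )
    return segments, samples


@dataclass
class NmfResult:
    W: np.ndarray
    H: np.ndarray
    f: int
    objective_trace: np.ndarray
    silhouette_scores: pd.Series
    weak_structure: bool
    segment_assignments: pd.DataFrame
    sample_assignments: pd.DataFrame


def run_nmf(
    S: pd.DataFrame,
    f: Optional[int] = None,
    f_range: Iterable[int] = range(2, 11),
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> NmfResult:
    """Full sub-grouping: feature-number selection (unless ``f`` is given),
    factorization, and argmax assignments. ``S`` is segments x samples with
    1 = the cultivar retains the segment."""
    arr = S.to_numpy(float)
    if f is None:
        f, scores, weak = select_feature_number(
            arr, f_range=f_range, seed=seed, max_iter=max_iter, tol=tol
        )
    else:
        scores, weak = pd.Series({f: np.nan}), False
    W, H, trace = nmf_factorize(arr, f, seed=seed, max_iter=max_iter, tol=tol)
    seg_assign, smp_assign = assign_subgroups(W, H, list(S.index), list(S.columns))
    return NmfResult(W, H, f, trace, scores, weak, seg_assign, smp_assign)


def region_preference(
    H: np.ndarray,
    sample_ids: Sequence[str],
    regions: pd.Series,
) -> Tuple[pd.DataFrame, Optional[np.ndarray], Sequence[str]]:
    """Median feature-sample score per region, with a region dendrogram.

    Returns (table, linkage, leaf_order): the table is regions x features
    of median H scores; the linkage is an average-linkage hierarchical
    clustering of the region rows (None with fewer than 2 regions).
    """
    H = np.asarray(H, float)
    reg = regions.reindex(sample_ids)
    if reg.isna().any():
        raise ValueError("every sample must carry a region label")
    df = pd.DataFrame(H.T, index=list(sample_ids))
    df["region"] = reg.to_numpy()
    table = df.groupby("region").median()
    table.columns = [f"SG{j + 1}" for j in range(H.shape[0])]
    if len(table) < 2:
        return table, None, list(table.index)
    Z = hierarchy.linkage(table.to_numpy(), method="average")
    order = [table.index[i] for i in hierarchy.leaves_list(Z)]
    return table, Z, order


def designate_sg(
    segment_assignments: pd.DataFrame, effects: pd.DataFrame
) -> Dict[int, str]:
    """Name sub-groups so SG1 is the one with the higher favorable fraction.

    ``effects`` needs columns segment_id and effect (FAVORABLE/DELETERIOUS).
    Returns a mapping from the numeric sub-group to "SG1"/"SG2"/...;
    override by passing your own mapping downstream.
    """
    lab = effects[effects["effect"].isin(["FAVORABLE", "DELETERIOUS"])]
    # one label per segment: a segment significant for several traits keeps
    # its first (file-order) oriented label
    eff = lab.drop_duplicates("segment_id").set_index("segment_id")["effect"]
    fracs = {}
    for sub, grp in segment_assignments.groupby("subgroup"):
        labels = eff.reindex(grp["segment_id"]).dropna()
        n_fav = (labels == "FAVORABLE").sum()
        n_tot = labels.isin(["FAVORABLE", "DELETERIOUS"]).sum()
        fracs[sub] = n_fav / n_tot if n_tot else -1.0
    ranked = sorted(fracs, key=lambda s: (-fracs[s], s))
    return {sub: f"SG{i + 1}" for i, sub in enumerate(ranked)}


def sg_ratio_vs_trait(
    segment_assignments: pd.DataFrame,
    matrix,
    trait: pd.Series,
    sg1: int = 1,
    sg2: int = 2,
    samples: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, float, float]:
    """Per-sample SG1/SG2 presence ratio against the median-normalized trait.

    ratio = (# SG1 segments present) / max(# SG2 segments present, 1); the
    zero-denominator guard is logged. Returns (per-sample table, Pearson r,
    P of r).
    """
    cols = list(samples) if samples is not None else list(matrix.data.columns)
    cols = [s for s in cols if s in trait.dropna().index]
    med = float(trait.loc[cols].median())
    if med == 0:
        raise ValueError("median trait value is zero; cannot normalize")
    sg1_ids = segment_assignments.loc[
        segment_assignments["subgroup"] == sg1, "segment_id"
    ]
    sg2_ids = segment_assignments.loc[
        segment_assignments["subgroup"] == sg2, "segment_id"
    ]
    d1 = (matrix.data.loc[sg1_ids, cols] == 1.0).sum(axis=0)
    d2 = (matrix.data.loc[sg2_ids, cols] == 1.0).sum(axis=0)
    if (d2 == 0).any():
        logger.info("%d samples have no SG2 segment; denominator clamped to 1",
                    int((d2 == 0).sum()))
    ratio = d1 / d2.clip(lower=1)
    norm_trait = trait.loc[cols] / med
    r, p = stats.pearsonr(ratio.to_numpy(float), norm_trait.to_numpy(float))
    table = pd.DataFrame(
        {"sample": cols, "sg1_count": d1.to_numpy(), "sg2_count": d2.to_numpy(),
         "ratio": ratio.to_numpy(), "trait_norm": norm_trait.to_numpy()}
    )
    return table, float(r), float(p)
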