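"""Non-redundant PAV map construction from dual-caller SV calls.

Two callers' per-sample call sets are intersected under a strict >50%
reciprocal-overlap rule, then the per-sample consensus sets are merged
across pedigree members into a non-redundant segment map by single-linkage
clustering under the same predicate. Insertions, whose length lives
off-reference, match by breakpoint proximity and length ratio instead.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ALT,
    CONTEXT_EXON,
    CONTEXT_INTERVAL,
    CONTEXT_INTRON,
    CONTEXT_PROMOTER,
    DEL,
    GeneModels,
    INS,
    PavRecord,
    PresenceMatrix,
    REF,
    SvCall,
    matrix_from_records,
)

# insertion-matching parameters (breakpoint proximity + length ratio); the
# interval rule does not apply to insertions, so this mirrors common
# SV-merging practice and is configurable at every call site
INS_MAX_DIST = 500
INS_MIN_LEN_RATIO = 0.5


def reciprocal_overlap(
    a,
    b,
    ins_max_dist: int = INS_MAX_DIST,
    ins_min_len_ratio: float = INS_MIN_LEN_RATIO,
) -> Tuple[float, float]:
    """Overlap fraction of each interval, ``(overlap/len_a, overlap/len_b)``.

    Calls on different chromosomes or of different SV types score (0, 0)
    rather than raising. Insertions return (1, 1) when breakpoints are
    within ``ins_max_dist`` bp and lengths agree within
    ``ins_min_len_ratio``, else (0, 0).
    """
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return (0.0, 0.0)
    if a.svtype == INS:
        close = abs(a.pos - b.pos) <= ins_max_dist
        ratio = min(a.length, b.length) / max(a.length, b.length)
        return (1.0, 1.0) if close and ratio >= ins_min_len_ratio else (0.0, 0.0)
    ov = min(a.end, b.end) - max(a.pos, b.pos) + 1
    if ov <= 0:
        return (0.0, 0.0)
    return (ov / a.length, ov / b.length)


def _passes(a, b, min_ro: float, **kw) -> bool:
    fa, fb = reciprocal_overlap(a, b, **kw)
    return fa > min_ro and fb > min_ro


def intersect_callers(
    calls_caller1: Sequence[SvCall],
    calls_caller2: Sequence[SvCall],
    min_ro: float = 0.5,
    ins_max_dist: int = INS_MAX_DIST,
    ins_min_len_ratio: float = INS_MIN_LEN_RATIO,
) -> List[SvCall]:
    """Per-sample dual-caller consensus.

    Greedy best-overlap matching: candidate pairs must exceed ``min_ro``
    reciprocally (strict), pairs are taken best-first, and each call is
    used at most once. Consensus coordinates come from caller 1 (the
    declared primary caller); unmatched calls are discarded.
    """
    kw = dict(ins_max_dist=ins_max_dist, ins_min_len_ratio=ins_min_len_ratio)
    by_key: Dict[tuple, List[SvCall]] = defaultdict(list)
    for c in calls_caller2:
        by_key[(c.chrom, c.svtype)].append(c)
    for v in by_key.values():
        v.sort(key=lambda c: (c.pos, c.end, c.length))

    pairs = []  # (score, i, j, call1)
    for i, a in enumerate(calls_caller1):
        for j, b in enumerate(by_key.get((a.chrom, a.svtype), ())):
            fa, fb = reciprocal_overlap(a, b, **kw)
            if fa > min_ro and fb > min_ro:
                pairs.append((min(fa, fb), i, j, a.chrom, a.svtype))
    # best-first, deterministic tie-break by coordinates
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1, used2 = set(), set()
    consensus = []
    for score, i, j, chrom, svtype in pairs:
        if i in used1 or (chrom, svtype, j) in used2:
            continue
        used1.add(i)
        used2.add((chrom, svtype, j))
        consensus.append(calls_caller1[i])
    consensus.sort(key=lambda c: (c.chrom, c.pos, c.end, c.svtype))
    return consensus


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _cluster_calls(
    calls: Sequence[SvCall],
    min_ro: float,
    ins_max_dist: int,
    ins_min_len_ratio: float,
) -> List[List[SvCall]]:
    """Single-linkage clusters under the overlap predicate (sweep-line)."""
    kw = dict(ins_max_dist=ins_max_dist, ins_min_len_ratio=ins_min_len_ratio)
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].svtype,
                                                     calls[i].pos, calls[i].end,
                                                     calls[i].sample, calls[i].caller))
    uf = _UnionFind(len(calls))
    active: List[int] = []
    prev_key = None
    for i in order:
        c = calls[i]
        key = (c.chrom, c.svtype)
        if key != prev_key:
            active = []
            prev_key = key
        horizon = c.pos - (ins_max_dist if c.svtype == INS else 0)
        active = [j for j in active if
                  (calls[j].end if calls[j].svtype == DEL else calls[j].pos + ins_max_dist)
                  >= horizon]
        for j in active:
            if _passes(calls[j], c, min_ro, **kw):
                uf.union(i, j)
        active.append(i)
    groups: Dict[int, List[SvCall]] = defaultdict(list)
    for i in order:
        groups[uf.find(i)].append(calls[i])
    return list(groups.values())


def merge_nonredundant(
    consensus_by_sample: Mapping[str, Sequence[SvCall]],
    roles: Mapping[str, str],
    regions: Optional[Mapping[str, str]] = None,
    foreign: Optional[Iterable[str]] = None,
    min_ro: float = 0.5,
    ins_max_dist: int = INS_MAX_DIST,
    ins_min_len_ratio: float = INS_MIN_LEN_RATIO,
    id_prefix: str = "PAV",
) -> Tuple[List[PavRecord], PresenceMatrix]:
    """Merge per-sample consensus calls into a non-redundant PAV map.

    Cross-sample single-linkage clustering under the same strict >``min_ro``
    reciprocal-overlap predicate; the longest member call represents each
    cluster. A sample is ALT at a record iff it contributed a call to the
    cluster, else REF; the presence-matrix entry is 1 iff REF.
    """
    if not consensus_by_sample:
        raise ValueError("need calls from at least one sample")
    pool: List[SvCall] = []
    for sample, calls in consensus_by_sample.items():
        pool.extend(calls)
    clusters = _cluster_calls(pool, min_ro, ins_max_dist, ins_min_len_ratio)
    # deterministic output order: by representative locus
    reps = []
    for cl in clusters:
        rep = max(cl, key=lambda c: (c.length, -c.pos, c.sample, c.caller))
        reps.append((rep, cl))
    reps.sort(key=lambda t: (t[0].chrom, t[0].pos, t[0].end, t[0].svtype))

    records = []
    for k, (rep, cl) in enumerate(reps):
        alleles = {s: REF for s in roles}
        for c in cl:
            alleles[c.sample] = ALT
        records.append(
            PavRecord(
                id=f"{id_prefix}{k + 1:05d}",
                chrom=rep.chrom,
                pos=rep.pos,
                end=rep.end,
                svtype=rep.svtype,
                length=rep.length,
                alleles=alleles,
            )
        )
    matrix = matrix_from_records(records, roles, regions=regions, foreign=foreign)
    return records, matrix


def pan_core_curve(
    matrix: PresenceMatrix, n_perm: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Pan/core saturation over random sample orderings.

    A sample *holds* a segment when it is ALT (carries the variation).
    For each k, pan(k) = mean |union of ALT sets of the first k samples|
    and core(k) = mean |intersection| over ``n_perm`` shuffles.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    A = (matrix.data.to_numpy() == 0.0).T  # samples x segments, True = ALT
    n_samples = A.shape[0]
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    pan = np.zeros((n_perm, n_samples))
    core = np.zeros((n_perm, n_samples))
    for p in range(n_perm):
        order = rng.permutation(n_samples)
        cum_or = np.logical_or.accumulate(A[order], axis=0)
        cum_and = np.logical_and.accumulate(A[order], axis=0)
        pan[p] = cum_or.sum(axis=1)
        core[p] = cum_and.sum(axis=1)
    return pd.DataFrame(
        {
            "k": np.arange(1, n_samples + 1),
            "mean_pan": pan.mean(axis=0),
            "mean_core": core.mean(axis=0),
        }
    )


class _IntervalIndex:
    """Per-chromosome sorted-interval index answering 'overlaps any?'."""

    def __init__(self, df: pd.DataFrame) -> None:
        self._by_chrom = {}
        for chrom, grp in df.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            self._by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom: str, qstart: int, qend: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, run_max_end = entry
        i = np.searchsorted(starts, qend, side="right")
        return i > 0 and run_max_end[i - 1] >= qstart


def annotate_genomic_context(
    records: Sequence[PavRecord],
    gene_models: GeneModels,
    promoter_bp: int = 2000,
) -> pd.Series:
    """Classify each segment as exon, intron, promoter or interval.

    Priority exon > intron > promoter > interval. The promoter is the
    ``promoter_bp`` window immediately upstream of the transcription start,
    strand-aware. Insertions are points; deletions are intervals.
    """
    genes = gene_models.genes
    exon_idx = _IntervalIndex(
        gene_models.exons.rename(columns=str)[["chrom", "start", "end"]]
    )
    gene_idx = _IntervalIndex(genes[["chrom", "start", "end"]])
    fwd = genes[genes["strand"] == "+"]
    rev = genes[genes["strand"] == "-"]
    prom = pd.concat(
        [
            pd.DataFrame(
                {
                    "chrom": fwd["chrom"],
                    "start": np.maximum(1, fwd["start"] - promoter_bp),
                    "end": fwd["start"] - 1,
                }
            ),
            pd.DataFrame(
                {"chrom": rev["chrom"], "start": rev["end"] + 1,
                 "end": rev["end"] + promoter_bp}
            ),
        ],
        ignore_index=True,
    )
    prom = prom[prom["end"] >= prom["start"]]
    prom_idx = _IntervalIndex(prom)

    out = {}
    for rec in records:
        qs, qe = (rec.pos, rec.pos) if rec.svtype == INS else (rec.pos, rec.end)
        if exon_idx.overlaps(rec.chrom, qs, qe):
            out[rec.id] = CONTEXT_EXON
        elif gene_idx.overlaps(rec.chrom, qs, qe):
            out[rec.id] = CONTEXT_INTRON
        elif prom_idx.overlaps(rec.chrom, qs, qe):
            out[rec.id] = CONTEXT_PROMOTER
        else:
            out[rec.id] = CONTEXT_INTERVAL
    return pd.Series(out, name="context")
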