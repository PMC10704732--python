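"""Synthetic pedigree + population generator with full ground truth.

The generator emulates a backbone-cultivar pedigree design: a reference
cultivar, its two parents, 18 progenies, and a large diversity population
(733 cultivars by default) genotyped for ~13k biallelic presence/absence
segments. Every downstream stage of the pipeline (consensus merging,
source classification, PAV-GWAS, heredity, NMF sub-grouping, fingerprint
scoring, prediction) can be exercised against the planted truth.

Randomness: every operation derives an independent deterministic stream
from ``SimConfig.seed`` via ``numpy.random.default_rng([seed, k])``, so the
same config always yields bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ALT,
    BIPARENTAL,
    CATEGORIES,
    DEL,
    GeneModels,
    INS,
    MISSING,
    P1_INHERITED,
    P2_INHERITED,
    PavRecord,
    PresenceMatrix,
    REF,
    REF_SPECIFIC,
    ROLE_PARENT1,
    ROLE_PARENT2,
    ROLE_POPULATION,
    ROLE_PROGENY,
    ROLE_REFERENCE,
    SvCall,
    matrix_from_records,
)

REGIONS = ("H", "Y", "NW", "N")
_STREAM_SEGMENTS = 1
_STREAM_PHENO = 2
_STREAM_EXPR = 3
_STREAM_CALLS = 4


@dataclass
class TraitSpec:
    name: str
    higher_is_better: bool = True
    # baseline trait level (in SD units); real agronomic scales are
    # positive-valued, which keeps median normalization well-defined
    baseline: float = 50.0


@dataclass
class CallerNoise:
    """Breakpoint jitter and error rates applied per caller."""

    jitter_sd: float = 10.0
    fp_rate: float = 0.02
    fn_rate: float = 0.02


@dataclass
class SimConfig:
    seed: int = 0
    n_segments: int = 13138
    n_progeny: int = 18
    n_population: int = 733
    # order: (P1_INHERITED, P2_INHERITED, REF_SPECIFIC, BIPARENTAL)
    category_props: Tuple[float, float, float, float] = (0.15, 0.15, 0.20, 0.50)
    # probability a progeny retains the reference segment, per category;
    # reference-specific segments are the least stably transmitted
    transmission_prob: Tuple[float, float, float, float] = (0.75, 0.75, 0.45, 0.90)
    # population presence-frequency range per category
    pop_freq_range: Tuple[Tuple[float, float], ...] = (
        (0.10, 0.60),
        (0.10, 0.60),
        (0.02, 0.30),
        (0.30, 0.90),
    )
    n_functional: int = 30
    effect_size_sd_units: float = 1.0
    effect_sign_prob: float = 0.6
    traits: Tuple[TraitSpec, ...] = (
        TraitSpec("fiber_length", True),
        TraitSpec("disease_index", False),
    )
    trait_noise_sd: float = 1.0
    n_genes: int = 200
    cis_effect_sd_units: float = 1.0
    expr_noise_sd: float = 1.0
    # probability a planted expression link's sign agrees with the planted
    # trait effect (yields a mix of consistent and conflict triplets)
    sgp_consistent_prob: float = 0.75
    region_props: Dict[str, float] = field(
        default_factory=lambda: {"H": 0.30, "Y": 0.30, "NW": 0.25, "N": 0.15}
    )
    # per-region presence-probability multipliers for the two planted
    # sub-groups of functional segments
    sg_enrichment: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "SG1": {"H": 1.3, "Y": 0.4, "NW": 1.3, "N": 1.3},
            "SG2": {"H": 0.4, "Y": 1.6, "NW": 0.4, "N": 0.4},
        }
    )
    sg_props: Tuple[float, float] = (0.6, 0.4)
    # when True, SG1 functional segments are planted favorable and SG2
    # deleterious on their trait (geographic sub-groups of opposed effect);
    # otherwise signs are Bernoulli(effect_sign_prob)
    sg_effect_polarity: bool = True
    fp_planted: int = 30
    caller_noise: CallerNoise = field(default_factory=CallerNoise)
    missing_rate: float = 0.0
    foreign_prop: float = 0.0
    # synthetic genome geometry (scaled-down, two chromosomes)
    n_chromosomes: int = 2
    chromosome_length: int = 60_000_000
    mean_gene_length: int = 3000
    exons_per_gene: int = 3
    max_segment_length: int = 5000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.category_props) - 1.0) > 1e-9:
            raise ValueError("category_props must sum to 1")
        if abs(sum(self.region_props.values()) - 1.0) > 1e-9:
            raise ValueError("region_props must sum to 1")
        for p in (*self.category_props, *self.transmission_prob,
                  self.effect_sign_prob, self.missing_rate, self.foreign_prop,
                  self.caller_noise.fp_rate, self.caller_noise.fn_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for lo, hi in self.pop_freq_range:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("pop_freq_range bounds must satisfy 0 <= lo <= hi <= 1")
        if self.n_functional > self.n_segments:
            raise ValueError("n_segments < n_functional")
        if self.n_functional + self.fp_planted > self.n_segments:
            raise ValueError("fingerprint + functional segments exceed n_segments")
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes")

    @property
    def n_pedigree(self) -> int:
        """Pedigree member count: two parents plus the progenies."""
        return 2 + self.n_progeny

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted truth for every simulated segment.

    ``segments`` has one row per segment: id, chrom, pos, end, svtype,
    length, category, is_functional, is_fingerprint, subgroup, trait,
    effect_sd (signed, oriented so positive = favorable), gene_id of the
    planted cis link and expr_shift (signed log-units).
    """

    segments: pd.DataFrame
    genes: GeneModels
    samples: pd.DataFrame  # sample, role, region, foreign

    @property
    def links(self) -> pd.DataFrame:
        f = self.segments[self.segments["gene_id"].notna()]
        return f[["id", "gene_id", "expr_shift"]].rename(columns={"id": "segment_id"})


class Simulation(NamedTuple):
    records: List[PavRecord]
    truth: GroundTruth
    matrix: PresenceMatrix


def _sample_names(config: SimConfig) -> Tuple[str, str, str, List[str], List[str]]:
    ref = "REF_CULTIVAR"
    p1, p2 = "Parent1", "Parent2"
    prog = [f"Progeny{i + 1:02d}" for i in range(config.n_progeny)]
    pop = [f"Pop{i + 1:04d}" for i in range(config.n_population)]
    return ref, p1, p2, prog, pop


def _draw_lengths(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    lens = np.exp(rng.normal(math.log(300.0), 1.0, size=n))
    return np.clip(np.round(lens), 20, config.max_segment_length).astype(int)


def _place_genes(
    rng: np.random.Generator, config: SimConfig, reserved: Sequence[Tuple[str, int, int]]
) -> GeneModels:
    """Place genes uniformly; ``reserved`` spans get genes planted around/near
    them (the cis partners of functional segments)."""
    rows, exon_rows = [], []
    gid = 0

    def add_gene(chrom: str, start: int, strand: str) -> str:
        nonlocal gid
        gid += 1
        name = f"GENE{gid:05d}"
        glen = max(600, int(rng.normal(config.mean_gene_length, config.mean_gene_length / 4)))
        end = start + glen - 1
        rows.append((name, chrom, start, end, strand))
        # alternate exon/intron blocks of equal size
        n_blocks = 2 * config.exons_per_gene - 1
        bounds = np.linspace(start, end + 1, n_blocks + 1).astype(int)
        for b in range(0, n_blocks, 2):
            exon_rows.append((name, chrom, int(bounds[b]), int(bounds[b + 1] - 1)))
        return name

    linked = []
    for chrom, s_pos, s_end in reserved:
        if rng.random() < 0.5:
            # gene spans the segment (genic context)
            start = max(1, s_pos - int(rng.integers(100, 1000)))
        else:
            # gene downstream of the segment, within the cis window
            start = s_end + int(rng.integers(500, 40_000))
        linked.append(add_gene(chrom, start, "+" if rng.random() < 0.5 else "-"))

    n_rest = config.n_genes - len(reserved)
    if n_rest < 0:
        raise ValueError("n_genes smaller than the number of requested links")
    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    for _ in range(n_rest):
        chrom = chroms[int(rng.integers(config.n_chromosomes))]
        start = int(rng.integers(1, config.chromosome_length - 50_000))
        add_gene(chrom, start, "+" if rng.random() < 0.5 else "-")

    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    models = GeneModels(genes, exons)
    models.genes.attrs["linked_order"] = linked
    return models


def simulate_segments(config: SimConfig) -> Simulation:
    """Draw the PAV map, pedigree and population genotypes, and truth.

    Segments sit on a jittered grid so that distinct true segments never
    satisfy the reciprocal-overlap merge predicate against each other;
    parental alleles are fully determined by the drawn source category,
    progeny alleles are i.i.d. Bernoulli with the per-category transmission
    probability, and population alleles follow per-category frequencies
    (modulated by region enrichment for planted sub-group segments).
    """
    config.validate()
    rng = config.rng(_STREAM_SEGMENTS)
    n = config.n_segments
    ref, p1, p2, prog, pop = _sample_names(config)

    # --- positions: jittered grid, round-robin across chromosomes --------
    chroms_all = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    per_chrom = math.ceil(n / config.n_chromosomes)
    spacing = config.chromosome_length / (per_chrom + 1)
    jitter_amp = max(0.0, (spacing - config.max_segment_length - 600) / 2)
    chrom_idx = np.arange(n) % config.n_chromosomes
    slot = np.arange(n) // config.n_chromosomes
    pos = ((slot + 1) * spacing + rng.uniform(-jitter_amp, jitter_amp, size=n)).astype(int)
    pos = np.maximum(pos, 1)
    lengths = _draw_lengths(rng, n, config)
    svtype = np.where(rng.random(n) < 0.5, DEL, INS)
    end = np.where(svtype == DEL, pos + lengths - 1, pos)

    # --- categories and planted roles ------------------------------------
    cat_idx = rng.choice(4, size=n, p=list(config.category_props))
    special = rng.choice(n, size=config.n_functional + config.fp_planted, replace=False)
    functional = np.zeros(n, bool)
    functional[special[: config.n_functional]] = True
    fingerprint = np.zeros(n, bool)
    fingerprint[special[config.n_functional:]] = True
    cat_idx[fingerprint] = CATEGORIES.index(BIPARENTAL)
    categories = np.array(CATEGORIES, dtype=object)[cat_idx]

    # --- gene models, with cis partners for functional segments ----------
    func_order = np.flatnonzero(functional)
    reserved = [
        (chroms_all[chrom_idx[i]], int(pos[i]), int(end[i] if svtype[i] == DEL else pos[i]))
        for i in func_order
    ]
    genes = _place_genes(rng, config, reserved)
    linked_genes = genes.genes.attrs["linked_order"]

    # --- planted effects, sub-groups, expression links -------------------
    trait_names = [t.name for t in config.traits]
    sg = np.array([None] * n, dtype=object)
    trait_of = np.array([None] * n, dtype=object)
    effect = np.full(n, 0.0)
    gene_of = np.array([None] * n, dtype=object)
    expr_shift = np.full(n, np.nan)
    sg_draw = rng.random(len(func_order))
    trait_draw = rng.integers(0, len(trait_names), size=len(func_order))
    sign_draw = rng.random(len(func_order))
    cons_draw = rng.random(len(func_order))
    for k, i in enumerate(func_order):
        sg[i] = "SG1" if sg_draw[k] < config.sg_props[0] else "SG2"
        trait_of[i] = trait_names[trait_draw[k]]
        if config.sg_effect_polarity:
            favorable = sg[i] == "SG1"
        else:
            favorable = sign_draw[k] < config.effect_sign_prob
        effect[i] = config.effect_size_sd_units * (1.0 if favorable else -1.0)
        gene_of[i] = linked_genes[k]
        agree = cons_draw[k] < config.sgp_consistent_prob
        expr_shift[i] = config.cis_effect_sd_units * (
            np.sign(effect[i]) if agree else -np.sign(effect[i])
        )

    # --- pedigree alleles -------------------------------------------------
    # parental alleles are determined by the category
    p1_ref = np.isin(categories, (P1_INHERITED, BIPARENTAL))
    p2_ref = np.isin(categories, (P2_INHERITED, BIPARENTAL))
    tprob = np.asarray(config.transmission_prob)[cat_idx]
    tprob = np.where(fingerprint, 1.0, tprob)
    prog_ref = rng.random((n, config.n_progeny)) < tprob[:, None]

    # --- population alleles ----------------------------------------------
    region_names = list(config.region_props)
    pop_regions = rng.choice(
        region_names, size=config.n_population, p=list(config.region_props.values())
    )
    freq_lo = np.array([config.pop_freq_range[c][0] for c in cat_idx])
    freq_hi = np.array([config.pop_freq_range[c][1] for c in cat_idx])
    base_freq = rng.uniform(freq_lo, freq_hi)
    prob = np.repeat(base_freq[:, None], config.n_population, axis=1)
    for sg_name, mult_map in config.sg_enrichment.items():
        seg_mask = sg == sg_name
        if not seg_mask.any():
            continue
        mult = np.array([mult_map.get(r, 1.0) for r in pop_regions])
        prob[seg_mask, :] = prob[seg_mask, :] * mult[None, :]
    prob = np.clip(prob, 0.005, 0.995)
    pop_ref = rng.random((n, config.n_population)) < prob
    # planted fingerprint segments: near-universal in the pedigree and
    # rare in the population (<= 7 carriers out of 733, scaled with the
    # cohort size so the tf-idf threshold geometry is preserved)
    fp_cap = max(1, (7 * config.n_population) // 733)
    for i in np.flatnonzero(fingerprint):
        k = int(rng.integers(1, fp_cap + 1))
        carriers = rng.choice(config.n_population, size=k, replace=False)
        row = np.zeros(config.n_population, bool)
        row[carriers] = True
        pop_ref[i] = row

    # --- assemble records, truth, matrix ---------------------------------
    ids = [f"SEG{i + 1:05d}" for i in range(n)]
    roles = {ref: ROLE_REFERENCE, p1: ROLE_PARENT1, p2: ROLE_PARENT2}
    roles.update({s: ROLE_PROGENY for s in prog})
    roles.update({s: ROLE_POPULATION for s in pop})
    samples = list(roles)

    code = np.empty((n, len(samples)))
    code[:, 0] = 1.0
    code[:, 1] = p1_ref.astype(float)
    code[:, 2] = p2_ref.astype(float)
    code[:, 3 : 3 + config.n_progeny] = prog_ref.astype(float)
    code[:, 3 + config.n_progeny :] = pop_ref.astype(float)
    if config.missing_rate > 0:
        miss = rng.random(code.shape) < config.missing_rate
        miss[:, 0] = False  # the reference is never missing
        miss[fingerprint, :] = False
        code[miss] = np.nan

    records = []
    ped_cols = samples[: 3 + config.n_progeny]
    for i in range(n):
        alleles = {}
        for j, s in enumerate(ped_cols):
            v = code[i, j]
            alleles[s] = MISSING if np.isnan(v) else (REF if v == 1.0 else ALT)
        records.append(
            PavRecord(
                id=ids[i],
                chrom=chroms_all[chrom_idx[i]],
                pos=int(pos[i]),
                end=int(end[i]),
                svtype=str(svtype[i]),
                length=int(lengths[i]),
                alleles=alleles,
            )
        )

    regions = dict(zip(pop, pop_regions))
    n_foreign = int(round(config.foreign_prop * config.n_population))
    foreign = set(rng.choice(pop, size=n_foreign, replace=False)) if n_foreign else set()
    data = pd.DataFrame(code, index=ids, columns=samples)
    matrix = PresenceMatrix(data, roles, regions=regions, foreign=foreign)

    seg_df = pd.DataFrame(
        {
            "id": ids,
            "chrom": [chroms_all[c] for c in chrom_idx],
            "pos": pos,
            "end": end,
            "svtype": svtype,
            "length": lengths,
            "category": categories,
            "is_functional": functional,
            "is_fingerprint": fingerprint,
            "subgroup": sg,
            "trait": trait_of,
            "effect_sd": effect,
            "gene_id": gene_of,
            "expr_shift": expr_shift,
        }
    )
    sample_df = pd.DataFrame(
        {
            "sample": samples,
            "role": [roles[s] for s in samples],
            "region": [regions.get(s) for s in samples],
            "foreign": [s in foreign for s in samples],
        }
    )
    truth = GroundTruth(segments=seg_df, genes=genes, samples=sample_df)
    return Simulation(records, truth, matrix)


def simulate_phenotypes(
    matrix: PresenceMatrix, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Additive phenotypes: carried reference segments contribute their
    planted effect (oriented so positive = favorable improves the trait),
    plus Gaussian noise of ``trait_noise_sd`` phenotype-SD units.

    Returns a samples x traits DataFrame.
    """
    rng = config.rng(_STREAM_PHENO)
    polar = {t.name: t.higher_is_better for t in config.traits}
    baseline = {t.name: t.baseline for t in config.traits}
    seg = truth.segments
    samples = list(matrix.data.columns)
    out = {}
    for trait in polar:
        rows = seg[(seg["trait"] == trait) & seg["is_functional"]]
        u = np.zeros(len(samples))
        if len(rows):
            presence = matrix.data.loc[rows["id"]].to_numpy()
            presence = np.nan_to_num(presence, nan=0.0)
            u = rows["effect_sd"].to_numpy() @ presence
        value = u if polar[trait] else -u
        value = baseline[trait] + value
        value = value + rng.normal(0.0, config.trait_noise_sd, size=len(samples))
        out[trait] = value
    unknown = set(seg.loc[seg["is_functional"], "trait"]) - set(polar)
    if unknown:
        raise ValueError(f"unknown trait polarity for {sorted(unknown)}")
    return pd.DataFrame(out, index=samples)


def simulate_expression(
    matrix: PresenceMatrix, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """TPM-like expression (genes x samples): log-normal noise around a
    per-gene baseline, with each planted cis link adding its signed shift
    (natural-log units) to carriers of the reference segment."""
    rng = config.rng(_STREAM_EXPR)
    gene_ids = list(truth.genes.genes["gene_id"])
    links = truth.links
    if links["gene_id"].nunique() < len(links):
        links = links.drop_duplicates("gene_id")
    if len(links) > len(gene_ids):
        raise ValueError("n_genes smaller than the number of requested links")
    samples = list(matrix.data.columns)
    baseline = rng.normal(math.log(10.0), 0.7, size=len(gene_ids))
    log_expr = np.repeat(baseline[:, None], len(samples), axis=1)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for _, row in links.iterrows():
        g = gidx.get(row["gene_id"])
        if g is None:
            continue
        presence = np.nan_to_num(matrix.data.loc[row["segment_id"]].to_numpy(), nan=0.0)
        log_expr[g] += row["expr_shift"] * presence
    log_expr = log_expr + rng.normal(0.0, config.expr_noise_sd, size=log_expr.shape)
    return pd.DataFrame(np.exp(log_expr), index=gene_ids, columns=samples)


def simulate_caller_calls(
    truth: GroundTruth, matrix: PresenceMatrix, config: SimConfig,
    callers: Tuple[str, str] = ("caller1", "caller2"),
) -> Dict[str, Dict[str, List[SvCall]]]:
    """Emit per-sample, per-caller SV call sets for the pedigree members.

    Every ALT allele (the sample carries the variation) produces one call
    per caller with Gaussian breakpoint jitter, dropped at the caller's
    false-negative rate; caller-private false positives are sprinkled
    uniformly over the genome. All calls respect the 20 bp floor.
    """
    noise = config.caller_noise
    rng = config.rng(_STREAM_CALLS)
    seg = truth.segments
    samples = matrix.pedigree_samples
    out: Dict[str, Dict[str, List[SvCall]]] = {c: {s: [] for s in samples} for c in callers}
    chrom_arr = seg["chrom"].to_numpy()
    pos_arr = seg["pos"].to_numpy()
    len_arr = seg["length"].to_numpy()
    type_arr = seg["svtype"].to_numpy()
    chroms_all = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    for caller in callers:
        for s in samples:
            col = matrix.data[s].to_numpy()
            alt_idx = np.flatnonzero(col == 0.0)
            keep = rng.random(len(alt_idx)) >= noise.fn_rate
            for i in alt_idx[keep]:
                p = int(pos_arr[i] + round(rng.normal(0.0, noise.jitter_sd)))
                p = max(1, p)
                ln = int(max(20, round(len_arr[i] + rng.normal(0.0, noise.jitter_sd))))
                if type_arr[i] == DEL:
                    call = SvCall(s, caller, chrom_arr[i], p, p + ln - 1, DEL, ln)
                else:
                    call = SvCall(s, caller, chrom_arr[i], p, p, INS, ln)
                out[caller][s].append(call)
            n_fp = rng.binomial(config.n_segments, noise.fp_rate)
            for _ in range(n_fp):
                chrom = chroms_all[int(rng.integers(config.n_chromosomes))]
                p = int(rng.integers(1, config.chromosome_length - config.max_segment_length))
                ln = int(_draw_lengths(rng, 1, config)[0])
                if rng.random() < 0.5:
                    call = SvCall(s, caller, chrom, p, p + ln - 1, DEL, ln)
                else:
                    call = SvCall(s, caller, chrom, p, p, INS, ln)
                out[caller][s].append(call)
            out[caller][s].sort(key=lambda c: (c.chrom, c.pos, c.end))
    return out


def simulate_structured_null(
    n_samples: int = 400,
    n_segments: int = 2000,
    trait_shift: float = 1.0,
    freq_shift: float = 0.3,
    seed: int = 0,
) -> Tuple[PresenceMatrix, pd.Series]:
    """A two-subpopulation null: segment frequencies differ between strata
    and the trait carries a between-stratum mean shift, but no segment has
    a true effect. Used to calibrate the PC-adjusted association scan."""
    rng = np.random.default_rng([seed, 99])
    strata = np.repeat([0, 1], [n_samples // 2, n_samples - n_samples // 2])
    p0 = rng.uniform(0.1, 0.9, size=n_segments)
    p1 = np.clip(p0 + rng.uniform(-freq_shift, freq_shift, size=n_segments), 0.02, 0.98)
    probs = np.where(strata[None, :] == 0, p0[:, None], p1[:, None])
    data = (rng.random((n_segments, n_samples)) < probs).astype(float)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    ids = [f"NULL{i + 1:05d}" for i in range(n_segments)]
    matrix = PresenceMatrix(
        pd.DataFrame(data, index=ids, columns=samples),
        {s: ROLE_POPULATION for s in samples},
    )
    trait = pd.Series(
        trait_shift * strata + rng.normal(0.0, 1.0, size=n_samples), index=samples
    )
    return matrix, trait


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["traits"] = [asdict(t) for t in config.traits]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "traits" in d:
        d["traits"] = tuple(TraitSpec(**t) for t in d["traits"])
    if "caller_noise" in d and isinstance(d["caller_noise"], dict):
        d["caller_noise"] = CallerNoise(**d["caller_noise"])
    for key in ("category_props", "transmission_prob", "sg_props"):
        if key in d:
            d[key] = tuple(d[key])
    if "pop_freq_range" in d:
        d["pop_freq_range"] = tuple(tuple(x) for x in d["pop_freq_range"])
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**d)
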