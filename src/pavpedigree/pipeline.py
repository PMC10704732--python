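"""Pipeline driver: simulate -> merge -> classify -> gwas -> heredity ->
subgroup -> fingerprint -> predict, with every stage's parameters and
outputs logged to a run manifest.

The population presence matrix is taken as an input (here produced by the
synthetic generator): short-read graph genotyping of a broad cohort is a
separate upstream concern. The merge stage therefore demonstrates the
dual-caller consensus on the pedigree members and cross-checks the
reconstructed pedigree map against the input matrix.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, classify, fingerprint, heredity, io, pavmap, predict, subgroup
from .core import PresenceMatrix
from .simulate import SimConfig, Simulation, config_from_dict, simulate_caller_calls, \
    simulate_expression, simulate_phenotypes, simulate_segments

logger = logging.getLogger(__name__)

STAGES = ("simulate", "merge", "classify", "gwas", "heredity", "subgroup",
          "fingerprint", "predict")


@dataclass
class RunConfig:
    """Run configuration; every threshold is echoed into the run manifest."""

    out_dir: str
    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    min_ro: float = 0.5
    alpha_marker: float = 0.01
    alpha_divergence: float = 0.05
    eqtl_alpha: float = 1e-3
    cis_window: int = 1_000_000
    promoter_bp: int = 2000
    fingerprint_threshold: float = 2.0
    tf_denominator: str = "members"
    f_min: int = 2
    f_max: int = 10
    k_folds: int = 5
    n_pcs: int = 2
    n_perm_pan: int = 50
    bottleneck_low: int = 6
    bottleneck_high: int = 12
    stages: Optional[List[str]] = None
    write_vcfs: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            raw["simulate"] = config_from_dict(sim)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Re-running with the same config reproduces identical outputs. Stages
    not in ``config.stages`` (when given) are skipped; dependents that
    cannot run without them are skipped with a reason in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = list(config.stages) if config.stages else list(STAGES)
    for s in wanted:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    manifest: Dict = {
        "pipeline": "pavpedigree",
        "seed": int(config.seed),
        "parameters": config.to_dict(),
        "stages": {},
    }

    def note(stage: str, status: str, **info):
        manifest["stages"][stage] = {"status": status, **info}
        logger.info("stage %s: %s", stage, status)

    # ---- base data (always generated: cheap and deterministic) ----------
    sim: Simulation = simulate_segments(config.simulate)
    phenos = simulate_phenotypes(sim.matrix, sim.truth, config.simulate)
    expr = simulate_expression(sim.matrix, sim.truth, config.simulate)
    matrix = sim.matrix
    polarities = {t.name: t.higher_is_better for t in config.simulate.traits}
    pop_samples = matrix.population_samples

    if "simulate" in wanted:
        io.write_matrix_tsv(matrix, out / "matrix.tsv", out / "samples.tsv")
        sim.truth.segments.to_csv(out / "truth_segments.tsv", sep="\t", index=False,
                                  na_rep="NA")
        phenos.rename_axis("sample").to_csv(out / "phenotypes.tsv", sep="\t",
                                            na_rep="NA")
        expr.rename_axis("gene_id").to_csv(out / "expression.tsv", sep="\t",
                                           float_format="%.4f")
        io.write_gff3(sim.truth.genes, out / "genes.gff3")
        io.write_pav_tsv(sim.records, out / "pav_truth.tsv")
        with open(out / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(manifest["parameters"]["simulate"], fh)
        note("simulate", "ok", n_segments=len(sim.records),
             n_samples=matrix.data.shape[1])

    contigs = {
        f"chr{c + 1}": config.simulate.chromosome_length
        for c in range(config.simulate.n_chromosomes)
    }

    merged_records = sim.records
    if "merge" in wanted:
        calls = simulate_caller_calls(sim.truth, matrix, config.simulate)
        c1, c2 = sorted(calls)
        if config.write_vcfs:
            vdir = out / "calls"
            vdir.mkdir(exist_ok=True)
            for caller, per_sample in calls.items():
                for sample, cs in per_sample.items():
                    io.write_sv_vcf(cs, vdir / f"{sample}.{caller}.vcf", contigs)
        consensus = {
            s: pavmap.intersect_callers(calls[c1][s], calls[c2][s], min_ro=config.min_ro)
            for s in matrix.pedigree_samples
        }
        roles = {s: matrix.roles[s] for s in matrix.samples_with_role(
            "reference", "parent1", "parent2", "progeny")}
        merged_records, ped_matrix = pavmap.merge_nonredundant(
            consensus, roles, min_ro=config.min_ro
        )
        io.write_pav_tsv(merged_records, out / "pav_merged.tsv")
        io.write_pav_vcf(merged_records, out / "pav_merged.vcf", contigs)
        pan = pavmap.pan_core_curve(
            ped_matrix.subset_samples(ped_matrix.pedigree_samples),
            n_perm=config.n_perm_pan, seed=config.seed,
        )
        pan.to_csv(out / "pan_core.tsv", sep="\t", index=False)
        note("merge", "ok", n_consensus_records=len(merged_records))

    contexts = pavmap.annotate_genomic_context(
        sim.records, sim.truth.genes, promoter_bp=config.promoter_bp
    )

    categories = None
    effects = None
    if "classify" in wanted:
        categories = classify.classify_sources(matrix)
        effects = classify.classify_effects(
            matrix, phenos.loc[pop_samples], polarities,
            alpha_divergence=config.alpha_divergence, samples=pop_samples,
        )
        ann = effects.merge(
            categories.rename("category"), left_on="segment_id", right_index=True
        )
        table, chi = classify.category_effect_table(ann)
        categories.rename("category").to_csv(out / "categories.tsv", sep="\t")
        effects.to_csv(out / "effects.tsv", sep="\t", index=False, na_rep="NA")
        table.to_csv(out / "category_effect_table.tsv", sep="\t", index=False,
                     na_rep="NA")
        chi.to_csv(out / "category_effect_chi2.tsv", sep="\t", index=False,
                   na_rep="NA")
        note("classify", "ok", n_classified=int((categories != "UNCLASSIFIED").sum()))

    pool = None
    eqtl = None
    if "gwas" in wanted:
        if effects is None:
            note("gwas", "skipped", reason="classify stage not run")
        else:
            assoc_frames = []
            for trait in phenos.columns:
                a = association.assoc_scan(
                    matrix, phenos[trait], n_pcs=config.n_pcs, samples=pop_samples
                )
                a["trait"] = trait
                a = a.drop(columns=["p_divergence"]).merge(
                    effects[effects["trait"] == trait][["segment_id", "p_divergence"]],
                    on="segment_id", how="left",
                )
                assoc_frames.append(a)
            assoc = pd.concat(assoc_frames, ignore_index=True)
            eqtl = association.eqtl_scan(
                matrix, expr, gene_models=sim.truth.genes, records=sim.records,
                cis_window=config.cis_window, n_pcs=config.n_pcs,
                samples=pop_samples,
            )
            pool = association.build_functional_pool(
                assoc, eqtl, contexts,
                alpha_marker=config.alpha_marker,
                alpha_divergence=config.alpha_divergence,
                eqtl_alpha=config.eqtl_alpha,
            )
            triplets = association.build_sgp_triplets(
                pool, eqtl, effects, eqtl_alpha=config.eqtl_alpha
            )
            pairs = association.pair_allelic(
                merged_records, matrix=None, trait=None
            )
            assoc.to_csv(out / "assoc.tsv", sep="\t", index=False, na_rep="NA")
            eqtl.to_csv(out / "eqtl.tsv", sep="\t", index=False, na_rep="NA")
            pool.to_csv(out / "functional_pool.tsv", sep="\t", index=False,
                        na_rep="NA")
            triplets.to_csv(out / "sgp_triplets.tsv", sep="\t", index=False)
            pairs.to_csv(out / "allelic_pairs.tsv", sep="\t", index=False,
                         na_rep="NA")
            note("gwas", "ok", pool_size=len(pool), n_triplets=len(triplets),
                 n_allelic_pairs=len(pairs))

    retention = None
    if "heredity" in wanted:
        retention = heredity.retention_counts(matrix)
        retention.to_csv(out / "retention.tsv", sep="\t", na_rep="NA")
        if categories is None:
            note("heredity", "partial", reason="classify stage not run; "
                 "stability comparison skipped")
        else:
            stab = heredity.stability_compare(retention, categories)
            stab.to_csv(out / "stability.tsv", sep="\t", index=False, na_rep="NA")
            bot = heredity.bottleneck_test(
                retention, config.bottleneck_low, config.bottleneck_high
            )
            note("heredity", "ok",
                 bottleneck={"mean_low": bot.mean_low, "mean_high": bot.mean_high,
                             "p_value": bot.p_value})

    if "subgroup" in wanted:
        if pool is None or effects is None:
            note("subgroup", "skipped", reason="gwas stage not run")
        else:
            func_ids = sorted(pool["segment_id"].unique())
            keep_samples = [s for s in pop_samples if s not in matrix.foreign]
            if len(func_ids) < 4:
                note("subgroup", "skipped", reason="functional pool too small")
            else:
                S = (matrix.data.loc[func_ids, keep_samples] == 1.0).astype(float)
                res = subgroup.run_nmf(
                    S, f_range=range(config.f_min, config.f_max + 1),
                    seed=config.seed,
                )
                naming = subgroup.designate_sg(res.segment_assignments, effects)
                res.segment_assignments.assign(
                    sg=lambda d: d["subgroup"].map(naming)
                ).to_csv(out / "subgroup_segments.tsv", sep="\t", index=False)
                res.sample_assignments.to_csv(out / "subgroup_samples.tsv",
                                              sep="\t", index=False)
                info = {"f_star": res.f, "weak_structure": res.weak_structure,
                        "silhouette": res.silhouette_scores.to_dict()}
                if matrix.regions is not None:
                    table, Z, order = subgroup.region_preference(
                        res.H, keep_samples, matrix.regions
                    )
                    table.to_csv(out / "region_preference.tsv", sep="\t")
                    info["region_order"] = list(order)
                lower_better = [t for t, hib in polarities.items() if not hib]
                if lower_better and res.f >= 2:
                    trait = lower_better[0]
                    inv = {v: k for k, v in naming.items()}
                    tab, r, p = subgroup.sg_ratio_vs_trait(
                        res.segment_assignments, matrix,
                        phenos.loc[keep_samples, trait],
                        sg1=inv.get("SG1", 1), sg2=inv.get("SG2", 2),
                        samples=keep_samples,
                    )
                    tab.to_csv(out / "sg_ratio.tsv", sep="\t", index=False)
                    info["sg_ratio_trait"] = trait
                    info["sg_ratio_pearson_r"] = r
                note("subgroup", "ok", **info)

    if "fingerprint" in wanted:
        scores = fingerprint.fingerprint_scores(
            matrix, threshold=config.fingerprint_threshold,
            tf_denominator=config.tf_denominator,
        )
        func_ids = pool["segment_id"].unique() if pool is not None else []
        overlay = fingerprint.pedigree_population_overlay(matrix, scores, func_ids)
        scores.to_csv(out / "fingerprint.tsv", sep="\t", na_rep="NA")
        overlay.to_csv(out / "overlay.tsv", sep="\t", na_rep="NA")
        note("fingerprint", "ok", n_fps=int(scores["is_fps"].sum()))

    if "predict" in wanted:
        if pool is None:
            note("predict", "skipped", reason="gwas stage not run")
        else:
            results = {}
            for trait in phenos.columns:
                feats = sorted(pool.loc[pool["trait"] == trait, "segment_id"].unique())
                if not feats:
                    results[trait] = None
                    continue
                rep = predict.fit_predict_trait(
                    matrix, feats, phenos.loc[pop_samples, trait],
                    k_folds=config.k_folds, seed=config.seed,
                    samples=pop_samples, trait_name=trait,
                )
                rep.predictions.rename("predicted").rename_axis("sample").to_csv(
                    out / f"predictions_{trait}.tsv", sep="\t"
                )
                results[trait] = {"pearson_r": rep.pearson_r,
                                  "p_value": rep.p_value,
                                  "n_features": len(feats)}
            note("predict", "ok", traits=results)

    io.write_report(manifest, out / "manifest.json")
    return out
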