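"""PAV map construction: overlap rule, consensus, merging, pan/core,
genomic-context annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pavpedigree as pp
from pavpedigree.core import GeneModels, PresenceMatrix, SvCall
from conftest import brute_force_clusters, truth_by_locus


def dele(pos, end, sample="s", caller="c", chrom="chr1"):
    return SvCall(sample, caller, chrom, pos, end, "DEL", end - pos + 1)


def ins(pos, length, sample="s", caller="c", chrom="chr1"):
    return SvCall(sample, caller, chrom, pos, pos, "INS", length)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a, b, want",
        [
            (dele(1001, 1200), dele(1001, 1200), (1.0, 1.0)),
            (dele(1001, 1200), dele(1101, 1300), (0.5, 0.5)),
            (dele(1001, 1200), dele(1051, 1260), (150 / 200, 150 / 210)),
            (dele(1001, 1200), dele(2001, 2200), (0.0, 0.0)),
        ],
    )
    def test_deletion_fractions(self, a, b, want):
        fa, fb = pp.reciprocal_overlap(a, b)
        assert fa == pytest.approx(want[0])
        assert fb == pytest.approx(want[1])

    def test_boundary_is_strict(self):
        # exactly half overlap fails the strict > 0.5 rule
        a, b = dele(1001, 1200), dele(1101, 1300)
        fa, fb = pp.reciprocal_overlap(a, b)
        assert not (fa > 0.5 and fb > 0.5)

    def test_different_chromosome_returns_zero(self):
        a = dele(1001, 1200, chrom="chr1")
        b = dele(1001, 1200, chrom="chr2")
        assert pp.reciprocal_overlap(a, b) == (0.0, 0.0)

    @pytest.mark.parametrize(
        "a, b, match",
        [
            (ins(5000, 100), ins(5400, 80), True),     # close, similar length
            (ins(5000, 100), ins(5600, 100), False),   # too far
            (ins(5000, 100), ins(5100, 40), False),    # length ratio < 0.5
        ],
    )
    def test_insertion_rule(self, a, b, match):
        want = (1.0, 1.0) if match else (0.0, 0.0)
        assert pp.reciprocal_overlap(a, b) == want

    def test_symmetry(self):
        a, b = dele(1001, 1200), dele(1051, 1260)
        fa, fb = pp.reciprocal_overlap(a, b)
        fb2, fa2 = pp.reciprocal_overlap(b, a)
        assert (fa, fb) == (fa2, fb2)


class TestIntersectCallers:
    def test_disjoint_sets_give_empty_consensus(self):
        c1 = [dele(1000, 1500)]
        c2 = [dele(9000, 9500)]
        assert pp.intersect_callers(c1, c2) == []

    def test_identical_sets_give_identity(self):
        c1 = [dele(1000, 1500), ins(8000, 120), dele(20000, 20299)]
        c2 = [SvCall("s", "c2", c.chrom, c.pos, c.end, c.svtype, c.length)
              for c in c1]
        cons = pp.intersect_callers(c1, c2)
        assert sorted(cons, key=lambda c: c.pos) == sorted(c1, key=lambda c: c.pos)

    def test_each_call_used_once(self):
        # two caller1 calls both overlap one caller2 call; only one matches
        c1 = [dele(1000, 1999), dele(1100, 2099)]
        c2 = [dele(1000, 1999, caller="c2")]
        cons = pp.intersect_callers(c1, c2)
        assert cons == [dele(1000, 1999)]

    def test_planted_calls_survive_private_fps(self, noiseless_sim):
        cfg, sim = noiseless_sim
        from pavpedigree.simulate import CallerNoise, SimConfig

        cfg2 = SimConfig(**{**cfg.__dict__,
                            "caller_noise": CallerNoise(0.0, 0.05, 0.0)})
        calls = pp.simulate_caller_calls(sim.truth, sim.matrix, cfg2)
        s = sim.matrix.progeny_samples[0]
        n_true = int((sim.matrix.data[s] == 0.0).sum())
        cons = pp.intersect_callers(calls["caller1"][s], calls["caller2"][s])
        assert len(cons) == n_true


class TestMergeNonredundant:
    def test_single_sample_identity(self):
        calls = [dele(1000, 1500, sample="a"), ins(8000, 120, sample="a")]
        roles = {"ref": "reference", "a": "progeny", "b": "progeny"}
        records, matrix = pp.merge_nonredundant({"a": calls}, roles)
        assert len(records) == 2
        assert all(r.alleles["a"] == "ALT" for r in records)
        assert all(r.alleles["b"] == "REF" for r in records)
        assert (matrix.data.loc[:, "a"] == 0.0).all()
        assert (matrix.data.loc[:, "b"] == 1.0).all()

    def test_exact_duplicates_collapse(self):
        roles = {f"s{i}": "progeny" for i in range(5)}
        per_sample = {
            f"s{i}": [dele(7000, 7299, sample=f"s{i}")] for i in range(5)
        }
        records, _ = pp.merge_nonredundant(per_sample, roles)
        assert len(records) == 1
        assert sum(a == "ALT" for a in records[0].alleles.values()) == 5

    def test_permutation_invariance(self, noiseless_consensus):
        records, _ = noiseless_consensus
        # re-merge with reversed sample insertion order
        by_sample = {}
        for r in records:
            for s, a in r.alleles.items():
                if a == "ALT":
                    by_sample.setdefault(s, []).append(
                        SvCall(s, "c1", r.chrom, r.pos, r.end, r.svtype, r.length)
                    )
        roles = {s: "progeny" for s in by_sample}
        fwd, _ = pp.merge_nonredundant(by_sample, roles)
        rev, _ = pp.merge_nonredundant(dict(reversed(list(by_sample.items()))), roles)
        key = lambda r: (r.chrom, r.pos, r.end, r.svtype)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_idempotence(self, noiseless_consensus):
        records, _ = noiseless_consensus
        per_sample = {}
        for r in records:
            for s, a in r.alleles.items():
                if a == "ALT":
                    per_sample.setdefault(s, []).append(
                        SvCall(s, "c1", r.chrom, r.pos, r.end, r.svtype, r.length)
                    )
        roles = {s: "progeny" for s in per_sample}
        again, _ = pp.merge_nonredundant(per_sample, roles)
        key = lambda r: (r.chrom, r.pos, r.end, r.svtype)
        assert sorted(map(key, again)) == sorted(
            key(r) for r in records if any(a == "ALT" for a in r.alleles.values())
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        calls = []
        for i in range(150):
            chrom = f"chr{rng.integers(1, 3)}"
            pos = int(rng.integers(1, 50_000))
            if rng.random() < 0.5:
                ln = int(rng.integers(20, 2000))
                calls.append(dele(pos, pos + ln - 1, sample=f"s{i % 7}", chrom=chrom))
            else:
                calls.append(ins(pos, int(rng.integers(20, 500)),
                                 sample=f"s{i % 7}", chrom=chrom))
        oracle = brute_force_clusters(calls)
        per_sample = {}
        for c in calls:
            per_sample.setdefault(c.sample, []).append(c)
        roles = {s: "progeny" for s in per_sample}
        records, _ = pp.merge_nonredundant(per_sample, roles)
        assert len(records) == len(oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pp.merge_nonredundant({}, {})


class TestPanCore:
    def make_matrix(self, arr, samples=None):
        arr = np.asarray(arr, float)
        samples = samples or [f"s{i}" for i in range(arr.shape[1])]
        return PresenceMatrix(
            pd.DataFrame(arr, columns=samples,
                         index=[f"g{i}" for i in range(arr.shape[0])]),
            {s: "progeny" for s in samples},
        )

    def test_identical_samples_flat_curves(self):
        m = self.make_matrix([[0, 0, 0], [1, 1, 1], [0, 0, 0]])
        out = pp.pan_core_curve(m, n_perm=5, seed=0)
        assert (out["mean_pan"] == 2).all()
        assert (out["mean_core"] == 2).all()

    def test_two_sample_enumeration(self):
        # ALT sets {s1, s2} and {s2, s3}: pan(2)=3, core(2)=1
        m = self.make_matrix([[0, 1], [0, 0], [1, 0]])
        out = pp.pan_core_curve(m, n_perm=20, seed=0)
        assert out.loc[1, "mean_pan"] == 3
        assert out.loc[1, "mean_core"] == 1

    def test_monotone(self, noiseless_sim):
        _, sim = noiseless_sim
        m = sim.matrix.subset_samples(sim.matrix.pedigree_samples)
        out = pp.pan_core_curve(m, n_perm=10, seed=1)
        assert (np.diff(out["mean_pan"]) >= 0).all()
        assert (np.diff(out["mean_core"]) <= 0).all()
        assert (out["mean_pan"] >= out["mean_core"]).all()


class TestGenomicContext:
    @pytest.fixture()
    def models(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 13_500],
                "end": [13_000, 16_000],
                "strand": ["+", "-"],
            }
        )
        exons = pd.DataFrame(
            {
                "gene_id": ["gA", "gA", "gB"],
                "chrom": ["chr1"] * 3,
                "start": [10_000, 12_500, 15_500],
                "end": [10_500, 13_000, 16_000],
            }
        )
        return GeneModels(genes, exons)

    def rec(self, pos, end, svtype="DEL"):
        length = end - pos + 1 if svtype == "DEL" else 100
        return pp.PavRecord("x", "chr1", pos, end, svtype, length, {})

    @pytest.mark.parametrize(
        "pos, end, want",
        [
            (10_100, 10_200, "exon"),
            (11_000, 11_100, "intron"),
            (9_000, 9_100, "promoter"),       # within 2 kb upstream of gA
            (16_500, 16_600, "promoter"),     # downstream of gB (- strand)
            (7_999, 7_999, "interval"),       # 1 bp beyond the 2 kb promoter
            (5_000, 5_100, "interval"),
            (12_900, 13_600, "exon"),         # exon of gA beats intron of gB
        ],
    )
    def test_priority_and_boundaries(self, models, pos, end, want):
        out = pp.annotate_genomic_context([self.rec(pos, end)], models)
        assert out["x"] == want

    def test_promoter_boundary_exact(self, models):
        # gA promoter spans [8000, 9999]
        assert pp.annotate_genomic_context([self.rec(8_000, 8_000)], models)["x"] == "promoter"
        assert pp.annotate_genomic_context([self.rec(7_999, 7_999)], models)["x"] == "interval"

    def test_malformed_gene_model_rejected(self):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "start": [100],
             "end": [50], "strand": ["+"]}
        )
        with pytest.raises(ValueError, match="malformed"):
            GeneModels(genes, genes[["gene_id", "chrom", "start", "end"]])


@settings(max_examples=30, deadline=None)
@given(
    pos1=st.integers(1, 10_000),
    len1=st.integers(20, 3000),
    pos2=st.integers(1, 10_000),
    len2=st.integers(20, 3000),
)
def test_overlap_fraction_bounds(pos1, len1, pos2, len2):
    a = dele(pos1, pos1 + len1 - 1)
    b = dele(pos2, pos2 + len2 - 1)
    fa, fb = pp.reciprocal_overlap(a, b)
    assert 0.0 <= fa <= 1.0 and 0.0 <= fb <= 1.0
    # overlap length is shared: fa * len_a == fb * len_b
    assert fa * a.length == pytest.approx(fb * b.length)
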