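"""Gene-set burden: capping, Jaccard on variant content, greedy step-down
vs exhaustive reference, resampling FDR arithmetic and calibration."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from uraburden.containers import GeneSet, GeneSetCollection, GeneSubjectMatrix
from uraburden.gene_burden import gene_binomial_test
from uraburden.geneset_burden import (
    filter_genesets,
    geneset_binomial_test,
    greedy_stepdown_select,
    jaccard_variant_similarity,
    resample_counts,
    resampling_fdr,
    run_geneset_tests,
)
from uraburden.mutation_model import RescaledModel


def make_model(p_success, n_subjects=100, n_obs=1):
    return RescaledModel(
        variant_class="truncating", sf=1.0, n_obs=n_obs,
        n_subjects=n_subjects, p_success=p_success,
    )


def make_matrix(entries, n_subjects=100):
    subjects = tuple(f"S{i:03d}" for i in range(n_subjects))
    m = GeneSubjectMatrix(variant_class="truncating", subject_ids=subjects)
    for gene, subject in entries:
        m.add(gene, subject)
    return m


def gs(name, *genes):
    return GeneSet(name=name, description="", genes=frozenset(genes))


class TestFilterGenesets:
    universe = [f"G{i}" for i in range(200)]

    def coll(self, *sets):
        return GeneSetCollection(sets=tuple(sets))

    @pytest.mark.parametrize("size,kept", [(5, False), (6, True), (99, True), (100, False)])
    def test_size_bounds_strict(self, size, kept):
        s = gs("S", *self.universe[:size])
        out = filter_genesets(self.coll(s), self.universe)
        assert (len(out) == 1) == kept

    def test_intersection_with_universe_counts(self):
        # 6 genes but only 5 in universe -> removed
        s = gs("S", *self.universe[:5], "NOT_IN_UNIVERSE")
        assert len(filter_genesets(self.coll(s), self.universe)) == 0

    def test_constrained_mode_needs_two_constrained_genes(self):
        s = gs("S", *self.universe[:10])
        one = filter_genesets(self.coll(s), self.universe, constrained_universe=["G0"])
        two = filter_genesets(self.coll(s), self.universe, constrained_universe=["G0", "G1"])
        assert len(one) == 0 and len(two) == 1


class TestGenesetBinomial:
    def test_subject_in_two_member_genes_counts_once(self):
        model = make_model({"A": 0.001, "B": 0.001, "C": 0.001}, n_obs=1)
        matrix = make_matrix([("A", "S000"), ("B", "S000")])
        res = geneset_binomial_test(model, matrix, gs("S", "A", "B"))
        assert res.n_success == 1

    def test_singleton_set_reduces_to_gene_test(self):
        model = make_model({"A": 0.002, "B": 0.001}, n_obs=1)
        matrix = make_matrix([("A", "S000"), ("A", "S001")])
        set_res = geneset_binomial_test(model, matrix, gs("S", "A"))
        gene_res = gene_binomial_test(model, matrix, "A")
        assert set_res.p_value == pytest.approx(gene_res.p_value, rel=1e-12)
        assert set_res.n_success == gene_res.n_success

    def test_three_gene_set_matches_bruteforce_tail(self):
        # 3 genes at 0.001, N_S = 100, 2 capped carriers -> Binomial(100, 0.003) tail
        model = make_model({"A": 0.001, "B": 0.001, "C": 0.001}, n_obs=1)
        matrix = make_matrix([("A", "S000"), ("C", "S001")])
        res = geneset_binomial_test(model, matrix, gs("S", "A", "B", "C"))
        p = 0.003
        oracle = sum(
            comb(100, k, exact=True) * p**k * (1 - p) ** (100 - k) for k in range(2, 101)
        )
        assert res.p_value == pytest.approx(oracle, rel=1e-12)

    def test_empty_after_intersection_errors(self):
        model = make_model({"A": 0.001}, n_obs=1)
        with pytest.raises(ValueError):
            geneset_binomial_test(model, make_matrix([]), gs("S", "X", "Y"))


class TestJaccard:
    def test_identity_disjoint_and_partial(self):
        matrix = make_matrix(
            [("A", "S000"), ("B", "S001"), ("C", "S002"), ("D", "S003")]
        )
        assert jaccard_variant_similarity(["A", "B"], ["A", "B"], matrix) == 1.0
        assert jaccard_variant_similarity(["A"], ["B"], matrix) == 0.0
        # variants {A,B,C} vs {B,C,D} -> 2/4
        assert jaccard_variant_similarity(["A", "B", "C"], ["B", "C", "D"], matrix) == 0.5

    def test_empty_union_is_zero(self):
        matrix = make_matrix([])
        assert jaccard_variant_similarity(["A"], ["B"], matrix) == 0.0

    def test_similarity_is_data_dependent(self):
        # heavy gene overlap but no shared observed variants -> 0
        matrix = make_matrix([("A", "S000")])
        assert jaccard_variant_similarity(["A", "B", "C"], ["B", "C", "D"], matrix) == 0.0


def exhaustive_reference_selection(results, matrix):
    """Reference greedy step-down: literal restatement with explicit pools."""
    remaining = sorted(results, key=lambda r: (r.p_value, r.name))
    reps = []
    while remaining:
        best = remaining[0]
        reps.append(best.name)
        keep = []
        for r in remaining[1:]:
            j = jaccard_variant_similarity(best.genes, r.genes, matrix)
            if j <= 0.5:
                keep.append(r)
        remaining = keep
    return reps


class TestGreedyStepdown:
    def run_selection(self, specs, entries):
        """specs: list of (name, genes, fake_p)."""
        genes = sorted({g for _, gg, _ in specs for g in gg})
        model = make_model({g: 0.001 for g in genes}, n_obs=1)
        matrix = make_matrix(entries)
        results = run_geneset_tests(
            model, matrix, GeneSetCollection(sets=tuple(gs(n, *gg) for n, gg, _ in specs))
        )
        # impose the intended p ordering via the observed counts instead of
        # patching: order asserted by caller
        return results, matrix

    def test_single_set_is_its_own_representative(self):
        results, matrix = self.run_selection(
            [("A", ["G1", "G2", "G3"], None)], [("G1", "S000")]
        )
        sel = greedy_stepdown_select(results, matrix)
        assert [c.representative.name for c in sel.clusters] == ["A"]

    def test_hand_traced_absorption(self):
        # A most significant; B shares variants with A (J > 0.5) -> absorbed;
        # C shares with B but not with A -> survives as second representative.
        entries = [
            ("G1", "S000"), ("G1", "S001"), ("G1", "S002"),  # A's signal
            ("G2", "S003"),  # shared by B and C
            ("G3", "S004"),  # C only
        ]
        specs = [
            ("A", ["G1", "G2"], None),   # variants {G1x3, G2} -> 4
            ("B", ["G1", "G2"], None),   # identical -> J(A,B) = 1
            ("C", ["G2", "G3"], None),   # {G2, G3}; J(A,C) = 1/5; J(B,C) = 1/5
        ]
        results, matrix = self.run_selection(specs, entries)
        sel = greedy_stepdown_select(results, matrix)
        reps = [c.representative.name for c in sel.clusters]
        assert reps[0] == "A"
        assert "B" in sel.clusters[0].absorbed
        assert "C" in reps

    def test_no_overlap_every_set_own_representative(self):
        entries = [("G1", "S000"), ("G2", "S001"), ("G3", "S002")]
        specs = [("A", ["G1"], None), ("B", ["G2"], None), ("C", ["G3"], None)]
        results, matrix = self.run_selection(specs, entries)
        sel = greedy_stepdown_select(results, matrix)
        assert len(sel.clusters) == 3
        ps = [c.representative.p_value for c in sel.clusters]
        assert ps == sorted(ps)

    def test_partition_property_and_exhaustive_equivalence(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(12)]
        for trial in range(20):
            n_sets = int(rng.integers(2, 7))
            specs = []
            for i in range(n_sets):
                size = int(rng.integers(1, 6))
                members = list(rng.choice(genes, size=size, replace=False))
                specs.append((f"SET{i}", members, None))
            entries = [
                (genes[int(rng.integers(0, 12))], f"S{int(rng.integers(0, 20)):03d}")
                for _ in range(int(rng.integers(1, 15)))
            ]
            model = make_model({g: 0.001 for g in genes}, n_obs=1, n_subjects=20)
            matrix = make_matrix(entries, n_subjects=20)
            results = run_geneset_tests(
                model, matrix,
                GeneSetCollection(sets=tuple(gs(n, *gg) for n, gg, _ in specs)),
            )
            sel = greedy_stepdown_select(results, matrix)
            # partition: every input set exactly once
            assert sorted(sel.all_set_names()) == sorted(r.name for r in results)
            # matches the independent reference implementation
            assert [c.representative.name for c in sel.clusters] == (
                exhaustive_reference_selection(results, matrix)
            )


class TestResampling:
    def model(self):
        return make_model(
            {f"G{i}": 0.001 * (i + 1) for i in range(10)}, n_subjects=50, n_obs=30
        )

    def test_total_preserved(self):
        model = self.model()
        for seed in range(5):
            matrix = resample_counts(model, seed=seed)
            assert matrix.raw_total == model.n_obs

    def test_seed_determinism(self):
        model = self.model()
        m1 = resample_counts(model, seed=11)
        m2 = resample_counts(model, seed=11)
        assert m1.counts == m2.counts

    def test_single_gene_universe(self):
        model = make_model({"G": 0.01}, n_subjects=50, n_obs=5)
        matrix = resample_counts(model, seed=0)
        assert matrix.counts.keys() == {"G"}
        assert sum(matrix.counts["G"].values()) == 5


class TestResamplingFDR:
    def setup_real(self, model, matrix, collection):
        results = run_geneset_tests(model, matrix, collection)
        return greedy_stepdown_select(results, matrix)

    def test_fdr_arithmetic_two_iterations(self):
        # Ngs_real = 2 at a threshold; permutation counts (0, 1) over two
        # iterations average to 0.5, giving raw FDR 0.5/2 = 0.25.
        from uraburden.geneset_burden import fdr_from_counts

        fdr = fdr_from_counts(np.array([0.5]), np.array([2]))
        assert fdr[0] == pytest.approx(0.25)

    def test_fdr_clamped_and_monotonized(self):
        from uraburden.geneset_burden import fdr_from_counts

        fdr = fdr_from_counts(np.array([0.1, 3.0, 1.0]), np.array([1, 2, 3]))
        assert list(fdr) == pytest.approx([0.1, 1 / 3, 1 / 3])

    def test_reproducible_given_seed(self):
        model = make_model({f"G{i}": 0.002 for i in range(20)}, n_subjects=50, n_obs=20)
        matrix = resample_counts(model, seed=3)
        coll = GeneSetCollection(
            sets=tuple(gs(f"S{i}", *[f"G{j}" for j in range(i, i + 6)]) for i in range(5))
        )
        real = self.setup_real(model, matrix, coll)
        f1 = resampling_fdr(real, model, coll, iterations=50, seed=9)
        f2 = resampling_fdr(real, model, coll, iterations=50, seed=9)
        assert f1 == f2

    def test_fdr_monotone_and_bounded(self):
        model = make_model({f"G{i}": 0.002 for i in range(20)}, n_subjects=50, n_obs=20)
        matrix = resample_counts(model, seed=5)
        coll = GeneSetCollection(
            sets=tuple(gs(f"S{i}", *[f"G{j}" for j in range(i, i + 6)]) for i in range(5))
        )
        real = self.setup_real(model, matrix, coll)
        fdr = resampling_fdr(real, model, coll, iterations=100, seed=1)
        vals = list(fdr.fdr)
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert vals == sorted(vals)  # non-decreasing toward weaker thresholds

    def test_iterations_below_one_error(self):
        model = make_model({"G0": 0.01}, n_subjects=50, n_obs=5)
        matrix = resample_counts(model, seed=0)
        coll = GeneSetCollection(sets=(gs("S", "G0"),))
        real = self.setup_real(model, matrix, coll)
        with pytest.raises(ValueError):
            resampling_fdr(real, model, coll, iterations=0)

    def test_two_seeds_agree_within_binomial_se(self):
        model = make_model({f"G{i}": 0.002 for i in range(20)}, n_subjects=100, n_obs=40)
        matrix = resample_counts(model, seed=21)
        coll = GeneSetCollection(
            sets=tuple(gs(f"S{i}", *[f"G{j}" for j in range(3 * i, 3 * i + 6)]) for i in range(5))
        )
        real = self.setup_real(model, matrix, coll)
        it = 1000
        fa = resampling_fdr(real, model, coll, iterations=it, seed=100)
        fb = resampling_fdr(real, model, coll, iterations=it, seed=200)
        for qa, qb in zip(fa.fdr, fb.fdr):
            q = max(min((qa + qb) / 2, 1.0), 1e-3)
            se = np.sqrt(q * (1 - q) / it)
            assert abs(qa - qb) <= max(3 * se, 0.05)
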