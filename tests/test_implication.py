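import numpy as np
import pandas as pd
import pytest
from scipy.stats.contingency import expected_freq

from boolimpl import implication as impl
from boolimpl.implication import QuadrantCounts, Relationship


def random_tables(rng, n, max_count=60):
    return rng.integers(0, max_count, size=(n, 4))


def transpose_counts(c: QuadrantCounts) -> QuadrantCounts:
    """Counts of the pair read in the other order (B, A)."""
    return QuadrantCounts(c.a00, c.a10, c.a01, c.a11)


def negate_b(c: QuadrantCounts) -> QuadrantCounts:
    """Counts after flipping every state of gene B."""
    return QuadrantCounts(c.a01, c.a00, c.a11, c.a10)


CONVERSE = {
    Relationship.NONE: Relationship.NONE,
    Relationship.EQUIVALENT: Relationship.EQUIVALENT,
    Relationship.OPPOSITE: Relationship.OPPOSITE,
    Relationship.LOLO: Relationship.HIHI,
    Relationship.HIHI: Relationship.LOLO,
    Relationship.LOHI: Relationship.LOHI,
    Relationship.HILO: Relationship.HILO,
}
NEGATION_DUAL = {
    Relationship.NONE: Relationship.NONE,
    Relationship.EQUIVALENT: Relationship.OPPOSITE,
    Relationship.OPPOSITE: Relationship.EQUIVALENT,
    Relationship.LOLO: Relationship.LOHI,
    Relationship.LOHI: Relationship.LOLO,
    Relationship.HIHI: Relationship.HILO,
    Relationship.HILO: Relationship.HIHI,
}


class TestCountQuadrants:
    def test_one_per_quadrant(self):
        c = impl.count_quadrants([-1, -1, 1, 1], [-1, 1, -1, 1])
        assert (c.a00, c.a01, c.a10, c.a11) == (1, 1, 1, 1)

    def test_intermediate_excluded_pairwise(self):
        c = impl.count_quadrants([-1, 0, 1], [-1, -1, 1])
        assert (c.a00, c.a01, c.a10, c.a11) == (1, 0, 0, 1)
        assert c.total == 2

    def test_all_intermediate(self):
        c = impl.count_quadrants([0, 0, 0], [0, 0, 0])
        assert c.total == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            impl.count_quadrants([0, 1], [0])


class TestQuadrantStatistics:
    def test_hand_example(self):
        stats = impl.quadrant_statistics(QuadrantCounts(0, 40, 40, 20))
        q00 = stats.loc["00"]
        assert q00["expected"] == pytest.approx(16.0)
        assert q00["S"] == pytest.approx(4.0)
        assert q00["p"] == pytest.approx(0.0)

    def test_perfect_independence(self):
        stats = impl.quadrant_statistics(QuadrantCounts(25, 25, 25, 25))
        assert stats["expected"].to_numpy() == pytest.approx([25.0] * 4)
        assert stats["S"].to_numpy() == pytest.approx([0.0] * 4)
        assert stats["p"].to_numpy() == pytest.approx([0.5] * 4)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            impl.quadrant_statistics(QuadrantCounts(0, 0, 10, 10))

    def test_expected_counts_match_contingency_oracle(self, rng):
        """Independence expectations equal scipy's contingency-table ones."""
        for a00, a01, a10, a11 in random_tables(rng, 1000):
            c = QuadrantCounts(int(a00), int(a01), int(a10), int(a11))
            try:
                stats = impl.quadrant_statistics(c)
            except ValueError:
                continue
            oracle = expected_freq([[a00, a01], [a10, a11]]).ravel()
            assert stats["expected"].to_numpy() == pytest.approx(oracle, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((0, 40, 40, 20), Relationship.LOHI),
            ((25, 25, 25, 25), Relationship.NONE),
            ((0, 50, 50, 0), Relationship.OPPOSITE),
            ((50, 0, 0, 50), Relationship.EQUIVALENT),
            ((50, 0, 30, 20), Relationship.LOLO),
            ((50, 30, 0, 20), Relationship.HIHI),
            ((20, 40, 40, 0), Relationship.HILO),
            ((0, 0, 40, 40), Relationship.NONE),  # zero margin: undefined
        ],
    )
    def test_reference_tables(self, counts, expected):
        assert impl.classify(QuadrantCounts(*counts)) == expected

    def test_converse_symmetry_exhaustive(self, rng):
        """relationship(B,A) is the converse of relationship(A,B)."""
        tables = random_tables(rng, 10_000)
        for a00, a01, a10, a11 in tables:
            c = QuadrantCounts(int(a00), int(a01), int(a10), int(a11))
            assert impl.classify(transpose_counts(c)) == CONVERSE[impl.classify(c)]

    def test_negation_duality_exhaustive(self, rng):
        tables = random_tables(rng, 10_000)
        for a00, a01, a10, a11 in tables:
            c = QuadrantCounts(int(a00), int(a01), int(a10), int(a11))
            assert impl.classify(negate_b(c)) == NEGATION_DUAL[impl.classify(c)]

    def test_sparsity_monotone_in_observed(self):
        """Lowering a quadrant's count (margins' other cells fixed) never
        decreases its S statistic."""
        base = QuadrantCounts(12, 30, 30, 30)
        s_prev = -np.inf
        for a00 in range(12, -1, -1):
            c = QuadrantCounts(a00, 30, 30, 30)
            s = impl.quadrant_statistics(c).loc["00", "S"]
            assert s >= s_prev
            s_prev = s
        del base

    def test_taxonomy_has_exactly_six_relationships(self):
        """Enumerating every sparse/dense quadrant pattern yields exactly
        the six recognized relationship categories."""
        seen = set()
        for mask in range(16):
            counts = [0 if mask & (1 << q) else 30 for q in range(4)]
            seen.add(impl.classify(QuadrantCounts(*counts)))
        assert seen - {Relationship.NONE} == set(Relationship.ALL)
        assert len(Relationship.ALL) == 6


class TestDynamicRangeFilter:
    def test_boundary_inclusive(self):
        row_removed = [-1] * 2 + [1] * 60 + [0] * 38  # 2% low
        row_kept = [-1] * 5 + [1] * 5 + [0] * 90  # exactly 5% both
        states = pd.DataFrame(
            [row_removed, row_kept], index=["weak", "edge"],
            columns=[f"s{i}" for i in range(100)],
        )
        kept = impl.dynamic_range_filter(states)
        assert list(kept) == ["edge"]

    def test_background_genes_removed(self, network_cohort):
        """Unimodal background genes fail the 5% dynamic-range rule."""
        from boolimpl.stepminer import discretize, threshold_matrix

        _, matrix, truth = network_cohort
        states = discretize(matrix, threshold_matrix(matrix))
        kept = impl.dynamic_range_filter(states)
        background = truth.block_membership[truth.block_membership == "BG"].index
        assert (kept.isin(background)).sum() <= 0.05 * len(background)


class TestAllPairs:
    def test_identical_genes_equivalent(self):
        rng = np.random.default_rng(3)
        s = rng.choice([-1, 1], size=60)
        states = pd.DataFrame([s, s], index=["a", "b"],
                              columns=[f"s{i}" for i in range(60)])
        edges = impl.all_pairs(states)
        assert len(edges) == 1
        assert edges.iloc[0]["relationship"] == Relationship.EQUIVALENT

    def test_mirrored_gene_opposite(self):
        rng = np.random.default_rng(3)
        s = rng.choice([-1, 1], size=60)
        states = pd.DataFrame([s, -s], index=["a", "b"],
                              columns=[f"s{i}" for i in range(60)])
        edges = impl.all_pairs(states)
        assert edges.iloc[0]["relationship"] == Relationship.OPPOSITE

    def test_matches_scalar_classify(self, rng):
        states = pd.DataFrame(
            rng.choice([-1, 0, 1], size=(8, 80)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(80)],
        )
        edges = impl.all_pairs(states)
        listed = {(r.gene_a, r.gene_b): r.relationship for r in edges.itertuples()}
        for i in range(8):
            for j in range(i + 1, 8):
                c = impl.count_quadrants(states.iloc[i], states.iloc[j])
                rel = impl.classify(c)
                key = (f"g{i}", f"g{j}")
                if rel == Relationship.NONE:
                    assert key not in listed
                else:
                    assert listed[key] == rel

    def test_planted_network_recovery(self, network_cohort):
        """All planted within/between-block relationships recovered, with no
        equivalent/opposite confusion."""
        from boolimpl.stepminer import discretize, threshold_matrix

        _, matrix, truth = network_cohort
        states = discretize(matrix, threshold_matrix(matrix))
        states = states.loc[impl.dynamic_range_filter(states)]
        edges = impl.all_pairs(states)
        found = {
            (r.gene_a, r.gene_b): r.relationship for r in edges.itertuples()
        }
        found.update(
            {(b, a): CONVERSE[rel] for (a, b), rel in list(found.items())}
        )
        planted = truth.planted_gene_edges()
        hits = sum(
            found.get((r.gene_a, r.gene_b)) == r.relationship
            for r in planted.itertuples()
        )
        assert hits / len(planted) >= 0.95
        symmetric = {Relationship.EQUIVALENT, Relationship.OPPOSITE}
        for r in planted.itertuples():
            got = found.get((r.gene_a, r.gene_b))
            if got is not None and r.relationship in symmetric:
                assert got == r.relationship


class TestPermutationFdr:
    def test_requires_permutations(self, tiny_matrix):
        with pytest.raises(ValueError, match="n_perm"):
            impl.permutation_fdr(tiny_matrix, n_perm=0)

    def test_planted_signal_low_fdr(self, network_cohort):
        _, matrix, _ = network_cohort
        sub = matrix.iloc[:40]
        fdr = impl.permutation_fdr(sub, n_perm=5, seed=5)
        assert fdr < 0.01

    def test_null_on_null_ratio_near_one(self, rng):
        """Fully permuted data scored against itself gives a ratio near 1."""
        null = pd.DataFrame(
            rng.normal(size=(30, 120)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(120)],
        )
        fdr = impl.permutation_fdr(null, n_perm=3, seed=1)
        assert fdr == np.inf or 0.1 < fdr < 10
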