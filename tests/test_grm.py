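"""GRM builders against hand calculations and brute-force oracles."""

import numpy as np
import pytest

from mafblup import (
    SnpRecord,
    allele_frequencies,
    build_grm_speed,
    build_grm_vanraden,
    build_grm_yang,
    compute_ld_weights,
    partition_grms_by_maf,
    regularize,
)
from mafblup.grm import read_gcta_grm, write_gcta_grm
from mafblup.population import GenotypePanel


def make_panel(dosages, positions=None, chroms=None, freqs=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = [
        SnpRecord(
            f"s{j}",
            int(chroms[j]) if chroms is not None else 1,
            int(positions[j]) if positions is not None else (j + 1) * 1000,
            float(freqs[j]) if freqs is not None else 0.25,
        )
        for j in range(m)
    ]
    return GenotypePanel([f"A{i}" for i in range(n)], snps, dosages)


def brute_force_vanraden(X):
    n, m = X.shape
    p = X.mean(axis=0) / 2
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            G[i, k] = sum((X[i, j] - 2 * p[j]) * (X[k, j] - 2 * p[j]) for j in range(m))
    return G / (2 * sum(pj * (1 - pj) for pj in p))


def brute_force_yang(X):
    n, m = X.shape
    p = X.mean(axis=0) / 2
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            G[i, k] = sum(
                (X[i, j] - 2 * p[j]) * (X[k, j] - 2 * p[j]) / (2 * p[j] * (1 - p[j]))
                for j in range(m)
            )
    return G / m


def brute_force_speed(X, w):
    n, m = X.shape
    p = X.mean(axis=0) / 2
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            G[i, k] = sum(
                w[j]
                * (X[i, j] - 2 * p[j])
                * (X[k, j] - 2 * p[j])
                / (2 * p[j] * (1 - p[j]))
                for j in range(m)
            )
    return G / sum(w)


@pytest.fixture(scope="module")
def random_dosages():
    rng = np.random.default_rng(77)
    while True:  # ensure every column polymorphic
        X = rng.binomial(2, rng.uniform(0.1, 0.9, 50), size=(10, 50)).astype(float)
        p = X.mean(axis=0) / 2
        if np.all((p > 0) & (p < 1)):
            return X


class TestAlleleFrequencies:
    def test_hand_cases(self):
        panel = make_panel(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
        p = allele_frequencies(panel)
        assert p[0] == pytest.approx(0.5)
        assert p[1] == 0.0  # monomorphic, flagged by validate()
        assert "monomorphic" in panel.validate()[0]

    def test_counting_oracle(self, rng):
        col = rng.integers(0, 3, 10).astype(float)
        panel = make_panel(col[:, None])
        assert allele_frequencies(panel)[0] == pytest.approx(col.sum() / 20)

    def test_missing_calls_excluded(self):
        col = np.array([0.0, 2.0, np.nan, 2.0])
        panel = make_panel(col[:, None])
        assert allele_frequencies(panel)[0] == pytest.approx(4 / 6)

    def test_empty_subset_rejected(self, small_panel):
        with pytest.raises(ValueError):
            allele_frequencies(small_panel, [])


class TestVanRaden:
    def test_two_animal_hand_case(self):
        """Dosages (0, 2): Z = (-1, 1), denominator 0.5, G = [[2,-2],[-2,2]]."""
        panel = make_panel(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(
            build_grm_vanraden(panel).matrix, [[2.0, -2.0], [-2.0, 2.0]]
        )

    def test_identical_animals_equal_rows(self):
        X = np.array([[0.0, 1, 2], [0, 1, 2], [2, 1, 0]])
        G = build_grm_vanraden(make_panel(X)).matrix
        np.testing.assert_allclose(G[0], G[1])

    def test_matches_brute_force(self, random_dosages):
        G = build_grm_vanraden(make_panel(random_dosages)).matrix
        np.testing.assert_allclose(G, brute_force_vanraden(random_dosages), atol=1e-10)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm_vanraden(make_panel(np.ones((3, 2)) * 2))


class TestYang:
    def test_two_animal_hand_case(self):
        panel = make_panel(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(
            build_grm_yang(panel).matrix, [[2.0, -2.0], [-2.0, 2.0]]
        )

    def test_single_snp_equals_vanraden(self, rng):
        col = np.array([0.0, 1, 1, 2, 0])
        panel = make_panel(col[:, None])
        np.testing.assert_allclose(
            build_grm_yang(panel).matrix, build_grm_vanraden(panel).matrix
        )

    def test_matches_brute_force(self, random_dosages):
        G = build_grm_yang(make_panel(random_dosages)).matrix
        np.testing.assert_allclose(G, brute_force_yang(random_dosages), atol=1e-10)

    def test_monomorphic_guard(self):
        X = np.column_stack([[0.0, 1, 2], [2.0, 2, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm_yang(make_panel(X))

    def test_agrees_with_vanraden_at_half_frequency(self):
        """Every SNP at p = 0.5: the two scalings coincide."""
        rngl = np.random.default_rng(5)
        while True:
            X = rngl.integers(0, 3, size=(8, 20)).astype(float)
            X = np.vstack([X, 2 - X])  # symmetrize so every column has p = 0.5
            if np.all(np.ptp(X, axis=0) > 0):
                break
        panel = make_panel(X)
        np.testing.assert_allclose(
            build_grm_yang(panel).matrix, build_grm_vanraden(panel).matrix, atol=1e-12
        )

    def test_mean_diagonal_near_one_for_unrelated(self, unrelated_panel):
        idx = np.where(unrelated_panel.maf() > 0.05)[0]
        G = build_grm_yang(unrelated_panel, idx).matrix
        assert abs(np.diag(G).mean() - 1.0) < 0.05

    def test_half_sib_off_diagonal_near_quarter(self):
        from mafblup import FamilySpec, make_snp_map, simulate_genotypes

        snps = make_snp_map(600, lo=0.1, seed=31)
        panel = simulate_genotypes(
            snps, 200, family=FamilySpec(n_sires=20), ld_decay=1e-9, seed=32
        )
        idx = np.where(panel.maf() > 0.05)[0]
        G = build_grm_yang(panel, idx).matrix
        sires = [panel.sire_of[a] for a in panel.animal_ids]
        vals = [
            G[i, j]
            for i in range(panel.n_animals)
            for j in range(i)
            if sires[i] == sires[j]
        ]
        assert abs(np.mean(vals) - 0.25) < 0.03


class TestPermutationEquivariance:
    @pytest.mark.parametrize("builder", [build_grm_vanraden, build_grm_yang])
    def test_relabeling_permutes_grm(self, builder, random_dosages):
        perm = np.random.default_rng(3).permutation(10)
        G = builder(make_panel(random_dosages)).matrix
        Gp = builder(make_panel(random_dosages[perm])).matrix
        np.testing.assert_allclose(Gp, G[np.ix_(perm, perm)], atol=1e-12)


class TestLdWeights:
    def test_independent_snps_get_unit_weights(self, unrelated_panel):
        idx = np.where(unrelated_panel.maf() > 0.1)[0][:60]
        w = compute_ld_weights(unrelated_panel, idx)
        assert np.all(w >= 0)
        # off-diagonal r2 ~ 1/n; system is near-identity
        np.testing.assert_allclose(w, 1.0, atol=0.25)

    def test_duplicate_pair_splits_weight(self):
        """Exact copies 1 bp apart: minimum-norm solution gives each 1/2."""
        col = np.array([0.0, 1, 2, 1, 0, 2, 1, 1])
        X = np.column_stack([col, col])
        panel = make_panel(X, positions=[1000, 1001])
        w = compute_ld_weights(panel)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-3)

    @pytest.mark.parametrize("q", [3, 5])
    def test_q_copies_share_one_unit(self, q):
        col = np.array([0.0, 1, 2, 1, 0, 2, 1, 1])
        panel = make_panel(
            np.tile(col[:, None], (1, q)), positions=[1000 + j for j in range(q)]
        )
        w = compute_ld_weights(panel)
        np.testing.assert_allclose(w, 1.0 / q, atol=5e-3)
        assert w.sum() == pytest.approx(1.0, abs=1e-3)

    def test_effective_locus_count(self):
        """Independent SNPs plus one triplicated block: sum k ~ effective loci."""
        rngl = np.random.default_rng(8)
        cols = [rngl.binomial(2, 0.4, 400).astype(float) for _ in range(6)]
        X = np.column_stack([cols[0], cols[0], cols[0]] + cols[1:])
        panel = make_panel(
            X, positions=[1000, 1001, 1002] + [1000 * (j + 2) for j in range(5)]
        )
        w = compute_ld_weights(panel)
        assert abs(w.sum() - 6.0) < 0.5

    def test_unsorted_subset_rejected(self, small_panel):
        with pytest.raises(ValueError, match="sorted"):
            compute_ld_weights(small_panel, [5, 3, 1])


class TestSpeed:
    def test_unit_weights_reduce_to_yang(self, random_dosages):
        panel = make_panel(random_dosages)
        G_s = build_grm_speed(panel, weights=np.ones(50)).matrix
        np.testing.assert_allclose(G_s, build_grm_yang(panel).matrix, atol=1e-12)

    def test_split_weights_equal_single_copy(self):
        col = np.array([0.0, 1, 2, 1, 0, 2])
        other = np.array([2.0, 1, 0, 1, 2, 0])
        dup = make_panel(np.column_stack([col, col, other]))
        single = make_panel(np.column_stack([col, other]))
        G_dup = build_grm_speed(dup, weights=np.array([0.5, 0.5, 1.0])).matrix
        G_single = build_grm_speed(single, weights=np.array([1.0, 1.0])).matrix
        np.testing.assert_allclose(G_dup, G_single, atol=1e-12)

    def test_matches_brute_force(self, random_dosages):
        w = np.random.default_rng(9).uniform(0.2, 2.0, 50)
        G = build_grm_speed(make_panel(random_dosages), weights=w).matrix
        np.testing.assert_allclose(G, brute_force_speed(random_dosages, w), atol=1e-10)

    def test_degenerate_weights_rejected(self, random_dosages):
        panel = make_panel(random_dosages)
        with pytest.raises(ValueError, match="zero"):
            build_grm_speed(panel, weights=np.zeros(50))
        with pytest.raises(ValueError):
            build_grm_speed(panel, weights=np.ones(10))


class TestPartition:
    def test_boundary_maf_goes_low(self):
        rngl = np.random.default_rng(11)
        X = np.column_stack(
            [
                np.repeat([0.0, 1.0], [90, 10]),  # p = 0.05 exactly
                rngl.binomial(2, 0.4, 100).astype(float),
            ]
        )
        g_low, g_high = partition_grms_by_maf(make_panel(X))
        assert g_low.snp_ids == ["s0"]
        assert g_high.snp_ids == ["s1"]
        assert g_low.kind == "partition_low" and g_high.kind == "partition_high"

    def test_strata_partition_the_subset(self, study_panel):
        idx = np.where(study_panel.maf() > 0)[0]
        g_low, g_high = partition_grms_by_maf(study_panel, idx)
        assert set(g_low.snp_ids) | set(g_high.snp_ids) == {
            study_panel.snps[i].snp_id for i in idx
        }
        assert not set(g_low.snp_ids) & set(g_high.snp_ids)

    def test_empty_stratum_named(self):
        X = np.random.default_rng(12).binomial(2, 0.4, size=(50, 5)).astype(float)
        with pytest.raises(ValueError, match="low"):
            partition_grms_by_maf(make_panel(X))


class TestRegularize:
    def test_zero_matrix_gets_jitter_diagonal(self):
        from mafblup.grm import Grm

        g = Grm(np.zeros((3, 3)), "yang", ["a", "b", "c"], ["s"])
        out = regularize(g)
        np.testing.assert_allclose(out.matrix, np.eye(3) * 1e-5)
        assert out.jitter == pytest.approx(1e-5)

    def test_trace_and_spectrum_shift(self, random_dosages):
        g = build_grm_yang(make_panel(random_dosages))
        out = regularize(g, 1e-5)
        assert np.trace(out.matrix) - np.trace(g.matrix) == pytest.approx(10 * 1e-5)
        ev_before = np.linalg.eigvalsh(g.matrix)
        ev_after = np.linalg.eigvalsh(out.matrix)
        np.testing.assert_allclose(ev_after, ev_before + 1e-5, atol=1e-12)
        # off-diagonals untouched
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_array_equal(out.matrix[off], g.matrix[off])


class TestGctaRoundTrip:
    def test_round_trip_identity(self, random_dosages, tmp_path):
        g = regularize(build_grm_yang(make_panel(random_dosages)))
        prefix = str(tmp_path / "test")
        write_gcta_grm(g, prefix)
        back = read_gcta_grm(prefix)
        np.testing.assert_allclose(back.matrix, g.matrix, rtol=1e-9)
        assert back.animal_ids == g.animal_ids
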