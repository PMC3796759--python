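"""SSI, SSI_c, SCI and the cross-trial synergy matching, checked against
brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from synstab import (
    SynergyDecomposition,
    SynergyEnsemble,
    compute_sci,
    compute_ssi,
    compute_ssic,
    ensemble_sci,
    match_synergies,
    pearson,
)
from conftest import unit_columns


def make_decomp(W, C=None):
    W = unit_columns(W)
    n = W.shape[1]
    if C is None:
        C = np.abs(np.sin(np.arange(1, n * 8 + 1, dtype=float))).reshape(n, 8)
    return SynergyDecomposition(W=W, C=np.asarray(C, dtype=float), L=100.0, n=n)


def brute_force_ssi(Ws):
    """Oracle: mean over synergies of the mean pairwise scipy Pearson r."""
    n = Ws[0].shape[1]
    vals = []
    for i in range(n):
        for l, q in itertools.combinations(range(len(Ws)), 2):
            vals.append(stats.pearsonr(Ws[l][:, i], Ws[q][:, i]).statistic)
    return float(np.mean(vals))


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([0, 1, 1], [0, 0, 1], 0.5),
        ],
    )
    def test_hand_examples(self, x, y, expected):
        assert pearson(np.array(x, float), np.array(y, float)) == pytest.approx(expected)

    @given(
        hnp.arrays(np.float64, 12, elements=st.floats(-10, 10)),
        hnp.arrays(np.float64, 12, elements=st.floats(-10, 10)),
    )
    @settings(max_examples=60, derandomize=True)
    def test_agrees_with_scipy(self, x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        expected = stats.pearsonr(x, y).statistic
        assert pearson(x, y) == pytest.approx(expected, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


class TestMatchSynergies:
    def test_unswaps_permuted_trial(self):
        W1 = unit_columns([[1.0, 0.0], [0.8, 0.1], [0.0, 1.0], [0.1, 0.9]])
        ens = SynergyEnsemble([make_decomp(W1), make_decomp(W1[:, ::-1])])
        perms = match_synergies(ens)
        assert perms == [(0, 1), (1, 0)]
        assert compute_ssi(ens) == pytest.approx(1.0)

    def test_identity_for_identical_trials(self):
        W = unit_columns(np.arange(1.0, 13.0).reshape(4, 3))
        ens = SynergyEnsemble([make_decomp(W)] * 3)
        assert match_synergies(ens) == [(0, 1, 2)] * 3

    def test_single_synergy_identity(self):
        W = unit_columns([[1.0], [2.0], [0.5]])
        ens = SynergyEnsemble([make_decomp(W), make_decomp(W * 2)])
        assert match_synergies(ens) == [(0,), (0,)]

    def test_matching_equals_exhaustive_search(self, rng):
        """The chosen permutation attains the exhaustive-search optimum of
        the summed per-synergy correlation with the reference trial."""
        n = 3
        decomps = [make_decomp(rng.random((6, n)) + 0.05) for _ in range(4)]
        ens = SynergyEnsemble(decomps)
        perms = match_synergies(ens)
        ref = decomps[0].W
        for j, d in enumerate(decomps):
            scores = {
                perm: sum(pearson(ref[:, i], d.W[:, perm[i]]) for i in range(n))
                for perm in itertools.permutations(range(n))
            }
            assert scores[perms[j]] == pytest.approx(max(scores.values()))

    def test_mismatched_n_rejected(self):
        d2 = make_decomp(np.ones((4, 2)) + np.eye(4, 2))
        d3 = make_decomp(np.ones((4, 3)) + np.eye(4, 3))
        with pytest.raises(ValueError):
            SynergyEnsemble([d2, d3])


class TestSSI:
    def test_identical_synergies_give_one(self):
        W = unit_columns([[0.9, 0.1], [0.3, 0.2], [0.1, 0.8], [0.2, 0.5]])
        ens = SynergyEnsemble([make_decomp(W) for _ in range(5)])
        assert compute_ssi(ens) == pytest.approx(1.0)

    def test_permutation_only_difference_gives_one(self):
        W = unit_columns([[1.0, 0.0], [0.7, 0.2], [0.1, 0.9], [0.0, 1.0]])
        ens = SynergyEnsemble([make_decomp(W), make_decomp(W[:, [1, 0]])])
        assert compute_ssi(ens) == pytest.approx(1.0)

    def test_equals_brute_force_on_hand_ensemble(self, rng):
        Ws = [unit_columns(rng.random((3, 2)) + 0.05) for _ in range(3)]
        ens = SynergyEnsemble([make_decomp(W) for W in Ws])
        ens.permutations = [(0, 1)] * 3  # fix alignment; compare raw statistic
        assert compute_ssi(ens) == pytest.approx(brute_force_ssi(Ws), abs=1e-9)

    def test_common_permutation_absorbed(self, rng):
        """Applying one column permutation to every trial leaves SSI
        unchanged after matching."""
        Ws = [unit_columns(rng.random((6, 3)) + 0.05) for _ in range(4)]
        ens_a = SynergyEnsemble([make_decomp(W) for W in Ws])
        ens_b = SynergyEnsemble([make_decomp(W[:, [2, 0, 1]]) for W in Ws])
        assert compute_ssi(ens_b) == pytest.approx(compute_ssi(ens_a), abs=1e-9)

    def test_decreases_with_synergy_perturbation(self):
        """Cross-trial synergy jitter sigma_W lowers SSI (checked over a
        few seeds at three jitter levels)."""
        from synstab import make_synergy_space

        means = []
        for sigma in (0.0, 0.15, 0.5):
            vals = []
            for seed in range(5):
                W_star = make_synergy_space(6, 2, 60.0, seed=seed)
                Ws = []
                for k in range(4):
                    rng = np.random.default_rng((seed, k))
                    jitter = rng.normal(0.0, sigma, size=W_star.shape) if sigma else 0.0
                    Ws.append(unit_columns(np.clip(W_star + jitter, 0.0, None)))
                ens = SynergyEnsemble([make_decomp(W) for W in Ws])
                vals.append(compute_ssi(ens))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_requires_two_trials(self):
        W = unit_columns([[1.0, 0.2], [0.2, 1.0]])
        with pytest.raises(ValueError):
            compute_ssi(SynergyEnsemble([make_decomp(W)]))


class TestSSIc:
    def test_identical_commands_give_one(self, rng):
        W = unit_columns(rng.random((4, 2)) + 0.05)
        C = rng.random((2, 10))
        ens = SynergyEnsemble([make_decomp(W, C) for _ in range(3)])
        assert compute_ssic(ens) == pytest.approx(1.0)

    def test_time_reversed_ramp_below_one(self):
        W = unit_columns([[1.0, 0.1], [0.1, 1.0], [0.5, 0.3]])
        ramp = np.vstack([np.linspace(0, 1, 8) ** 2, np.linspace(1, 0, 8) ** 3])
        ens = SynergyEnsemble(
            [make_decomp(W, ramp), make_decomp(W, ramp[:, ::-1])]
        )
        assert compute_ssic(ens) < 1.0

    def test_equals_pairwise_pearson_mean(self, rng):
        W = unit_columns(rng.random((5, 2)) + 0.05)
        C1 = rng.random((2, 4))
        C2 = rng.random((2, 4))
        ens = SynergyEnsemble([make_decomp(W, C1), make_decomp(W, C2)])
        expected = np.mean(
            [stats.pearsonr(C1[i], C2[i]).statistic for i in range(2)]
        )
        assert compute_ssic(ens) == pytest.approx(expected, abs=1e-9)


class TestSCI:
    def test_identical_columns_give_one(self):
        w = unit_columns([[0.1], [0.9], [0.3], [0.2], [0.0], [0.4]])
        W = np.hstack([w, w, w])
        assert compute_sci(W) == pytest.approx(1.0)

    def test_orthogonal_columns_give_zero(self):
        W = np.zeros((6, 2))
        W[0, 0] = 1.0
        W[3, 1] = 1.0
        assert compute_sci(W) == pytest.approx(0.0)

    def test_sixty_degree_pair_gives_half(self):
        theta = np.deg2rad(60.0)
        W = np.array([[1.0, np.cos(theta)], [0.0, np.sin(theta)]])
        assert compute_sci(W) == pytest.approx(0.5)

    def test_column_order_invariant(self, rng):
        W = unit_columns(rng.random((6, 3)) + 0.05)
        assert compute_sci(W[:, [2, 0, 1]]) == pytest.approx(compute_sci(W))

    def test_increases_as_pair_angle_shrinks(self):
        def pair(angle):
            t = np.deg2rad(angle)
            return np.array([[1.0, np.cos(t)], [0.0, np.sin(t)]])

        scis = [compute_sci(pair(a)) for a in (80.0, 60.0, 30.0, 10.0)]
        assert scis == sorted(scis)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True)
    def test_range_on_random_nonnegative_unit_columns(self, seed):
        rng = np.random.default_rng(seed)
        W = unit_columns(rng.random((5, 3)) + 1e-6)
        assert -1e-9 <= compute_sci(W) <= 1.0 + 1e-9

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            compute_sci(np.array([[1.0], [0.0]]))

    def test_non_unit_columns_rejected(self):
        with pytest.raises(ValueError):
            compute_sci(np.ones((4, 2)))

    def test_ensemble_sci_reports_per_trial(self, rng):
        Ws = [unit_columns(rng.random((6, 2)) + 0.05) for _ in range(3)]
        ens = SynergyEnsemble([make_decomp(W) for W in Ws])
        scis = ensemble_sci(ens)
        assert len(scis) == 3
        assert ens.sci_mean == pytest.approx(np.mean(scis))
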