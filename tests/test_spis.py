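import numpy as np
import pytest

from mtscompare import DIRECTED_SPIS, SPI_NAMES, compute_spi_tensor, make_pair_index
from mtscompare import spis as S
from mtscompare.features import zscore_series


@pytest.fixture(scope="module")
def noise_pair():
    rng = np.random.default_rng(11)
    return rng.normal(size=300), rng.normal(size=300)


def brute_force_dtw(x, y):
    """Plain recursive DTW definition, memoized; independent of the DP code."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0 and j == 0:
            return abs(x[0] - y[0])
        best = np.inf
        if i > 0:
            best = min(best, d(i - 1, j))
        if j > 0:
            best = min(best, d(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, d(i - 1, j - 1))
        return abs(x[i] - y[j]) + best

    return d(len(x) - 1, len(y) - 1)


class TestPairIndex:
    @pytest.mark.parametrize(
        "r,directed,expected",
        [(3, True, 6), (10, True, 90), (48, False, 1128), (48, True, 2256)],
    )
    def test_pair_counts(self, r, directed, expected):
        assert len(make_pair_index(r, directed)) == expected

    def test_row_major_order(self):
        idx = make_pair_index(3, directed=False)
        assert idx.pairs == [(0, 1), (0, 2), (1, 2)]

    def test_spi_catalog(self):
        assert len(SPI_NAMES) == 14
        assert len(DIRECTED_SPIS) == 7
        assert DIRECTED_SPIS < set(SPI_NAMES)


class TestPearsonAndDTW:
    def test_hand_values(self):
        assert S.pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert S.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert S.pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_dtw_identical_is_zero(self, noise_pair):
        x, _ = noise_pair
        assert S.dtw_distance(x, x) == 0.0

    def test_dtw_absorbs_shift(self):
        assert S.dtw_distance([0.0, 0, 1, 0], [0.0, 1, 0, 0]) == 0.0
        assert S.dtw_distance([0.0, 1], [1.0, 0]) == 2.0

    def test_dtw_matches_brute_force(self, rng):
        for _ in range(100):
            n, m = rng.integers(1, 7, size=2)
            x, y = rng.normal(size=n), rng.normal(size=m)
            assert S.dtw_distance(x, y) == pytest.approx(
                brute_force_dtw(tuple(x), tuple(y)), abs=1e-12
            )

    def test_barycenter_of_identical_pair(self, noise_pair):
        x, _ = noise_pair
        assert S.barycenter_statistic(x, x) == pytest.approx(x.max())


class TestSpectral:
    def test_self_coherence_and_pli(self, noise_pair):
        x, _ = noise_pair
        assert S.coherence_magnitude(x, x, 2.0) == pytest.approx(1.0)
        assert S.pli(x, x) == 0.0

    def test_quarter_cycle_lag_gives_high_pli(self):
        rng = np.random.default_rng(5)
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 20) + 0.05 * rng.normal(size=400)
        y = np.sin(2 * np.pi * (t - 5) / 20) + 0.05 * rng.normal(size=400)
        assert S.pli(x, y) > 0.95

    def test_independent_coherence_is_small_bias(self):
        vals = [
            S.coherence_magnitude(
                np.random.default_rng(i).normal(size=288),
                np.random.default_rng(1000 + i).normal(size=288),
                2.0,
            )
            for i in range(30)
        ]
        assert 0.1 < np.mean(vals) < 0.45  # positive Welch bias, far below 1

    def test_psi_exact_antisymmetry(self, noise_pair):
        x, y = noise_pair
        assert S.psi_frequency(x, y, 2.0) == pytest.approx(
            -S.psi_frequency(y, x, 2.0), rel=1e-12
        )
        assert S.psi_time_frequency(x, y, 2.0) == pytest.approx(
            -S.psi_time_frequency(y, x, 2.0), rel=1e-12
        )


class TestInformation:
    def test_te_matches_gaussian_closed_form(self):
        rng = np.random.default_rng(8)
        n = 200_000
        x = rng.normal(size=n)
        y = np.empty(n)
        y[0] = rng.normal()
        y[1:] = 0.5 * x[:-1] + rng.normal(size=n - 1)
        assert S.transfer_entropy(x, y) == pytest.approx(0.5 * np.log(1.25), abs=0.01)
        assert S.transfer_entropy(y, x) == pytest.approx(0.0, abs=0.005)

    def test_te_equals_determinant_oracle(self, rng):
        # independent code path: TE from covariance determinants
        for _ in range(10):
            x = rng.normal(size=200)
            y = rng.normal(size=200) + 0.3 * np.roll(x, 1)
            yt, yp, xp = y[1:], y[:-1], x[:-1]
            full = np.cov(np.vstack([yt, yp, xp]), ddof=1)
            det = np.linalg.det
            v_r = det(full[:2, :2]) / full[1, 1]
            v_f = det(full) / det(full[1:, 1:])
            oracle = 0.5 * np.log(v_r / v_f)
            assert S.transfer_entropy(x, y) == pytest.approx(oracle, abs=1e-10)

    def test_di_exceeds_te_by_instantaneous_term(self, rng):
        x = rng.normal(size=500)
        y = 0.6 * x + rng.normal(size=500)  # instantaneous coupling only
        assert S.directed_information(x, y) > S.transfer_entropy(x, y) + 0.05

    def test_phi_star_independent_near_zero(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        assert abs(S.phi_star(x, y)) < 0.01

    def test_phi_star_symmetric(self, noise_pair):
        x, y = noise_pair
        assert S.phi_star(x, y) == pytest.approx(S.phi_star(y, x), abs=1e-8)

    def test_phi_star_positive_for_coupled_system(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = np.zeros(n)
        y = np.zeros(n)
        ex, ey = rng.normal(size=(2, n))
        for t in range(1, n):
            x[t] = 0.4 * x[t - 1] + 0.4 * y[t - 1] + ex[t]
            y[t] = 0.4 * y[t - 1] + 0.4 * x[t - 1] + ey[t]
        assert S.phi_star(x, y) > 0.01


class TestCausal:
    def test_geweke_identity_on_var1(self):
        rng = np.random.default_rng(9)
        a = np.array([[0.5, 0.0], [0.4, 0.3]])
        n = 4000
        d = np.zeros((n, 2))
        eps = rng.normal(size=(n, 2))
        for t in range(1, n):
            d[t] = a @ d[t - 1] + eps[t]
        x, y = d[:, 0], d[:, 1]
        spectral_mean = S.spectral_granger(x, y, order=1)
        v_r = S._resid_var(y[1:], y[:-1][:, None])
        v_f = S._resid_var(y[1:], np.column_stack([y[:-1], x[:-1]]))
        time_domain = np.log(v_r / v_f)
        assert spectral_mean == pytest.approx(time_domain, rel=0.05)

    def test_independent_pair_has_negligible_gc(self, noise_pair):
        x, y = noise_pair
        assert S.spectral_granger(x, y, order=1) < 0.05

    def test_cointegration_detects_shared_trend(self):
        rng = np.random.default_rng(4)
        rw = np.cumsum(rng.normal(size=400))
        coupled = S.cointegration_stat(rw, rw + 0.5 * rng.normal(size=400))
        indep = np.median(
            [
                S.cointegration_stat(
                    np.cumsum(np.random.default_rng(i).normal(size=400)),
                    np.cumsum(np.random.default_rng(900 + i).normal(size=400)),
                )
                for i in range(15)
            ]
        )
        assert coupled < -6  # far inside the rejection region
        assert indep > -3  # typical spurious-regression statistic

    def test_anm_residuals_independent_under_true_direction(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=300)
        y = np.tanh(2 * x) + 0.3 * rng.normal(size=300)
        assert S.additive_noise_model(x, y) < S.additive_noise_model(y, x)


@pytest.fixture(scope="module")
def tensor(small_dataset):
    return compute_spi_tensor(small_dataset, ["pearson", "transfer_entropy", "PLI"])


class TestTensor:
    def test_pair_counts_by_directedness(self, tensor):
        assert tensor.values["pearson"].shape == (12, 3)  # 3 regions undirected
        assert tensor.values["transfer_entropy"].shape == (12, 6)

    def test_undirected_symmetry_via_swapped_pairs(self, small_dataset):
        z = {
            j: zscore_series(small_dataset.data[0, j]) for j in range(3)
        }
        for name in ("pearson", "PLI", "coherence_magnitude", "phi_star"):
            func = S._spi_func(name)
            v1 = func(z[0], z[1], 2.0)
            v2 = func(z[1], z[0], 2.0)
            assert v1 == pytest.approx(v2, rel=1e-6, abs=1e-8), name

    def test_unknown_spi_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown"):
            compute_spi_tensor(small_dataset, ["nope"])

    def test_h5_round_trip(self, tensor, tmp_path):
        from mtscompare.spis import read_spi_tensor_h5, write_spi_tensor_h5

        path = tmp_path / "spis.h5"
        write_spi_tensor_h5(tensor, path)
        back = read_spi_tensor_h5(path)
        assert set(back.spi_names) == set(tensor.spi_names)
        for name in tensor.spi_names:
            np.testing.assert_array_equal(back.values[name], tensor.values[name])
            assert back.pair_index[name].pairs == tensor.pair_index[name].pairs

    def test_bounds(self, tensor):
        assert np.all(np.abs(tensor.values["pearson"]) <= 1.0)
        assert np.all(tensor.values["PLI"] >= 0) and np.all(
            tensor.values["PLI"] <= 1
        )
        assert np.all(tensor.values["transfer_entropy"] > -1e-10)
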