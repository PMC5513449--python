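import numpy as np
import pytest

from icaclust import (
    DEFAULT_CLUSTER_SIZES,
    SimulationConfig,
    calibrate_phi,
    estimate_ar1,
    simulate_dataset,
)


def _lag1_corr(counts: np.ndarray) -> float:
    """Pooled Pearson correlation between adjacent time points."""
    pairs_x = counts[:, :-1].ravel()
    pairs_y = counts[:, 1:].ravel()
    return float(np.corrcoef(pairs_x, pairs_y)[0, 1])


class TestConfig:
    def test_default_scenario_shape(self):
        cfg = SimulationConfig()
        assert cfg.n_genes == 458
        assert cfg.cluster_sizes == DEFAULT_CLUSTER_SIZES == (89, 51, 153, 67, 40, 58)
        assert cfg.n_clusters == 6
        assert cfg.n_timepoints == 4
        assert cfg.n_replicates == 10

    @pytest.mark.parametrize(
        "override, message",
        [
            ({"phi": 1.0}, "phi"),
            ({"lambda_profiles": ((10.0, -1.0),), "cluster_sizes": (5,), "phi": 0.2}, "positive"),
            ({"cluster_sizes": (10, 0), "lambda_profiles": ((1.0, 2.0), (3.0, 4.0))}, "positive"),
            ({"lambda_cv": -0.1}, "lambda_cv"),
        ],
    )
    def test_invalid_configs_rejected(self, override, message):
        with pytest.raises(ValueError, match=message):
            SimulationConfig(**override)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=7, lambda_cv=0.2)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestSimulateDataset:
    def test_reproducible_bit_identical(self):
        cfg = SimulationConfig(seed=11)
        a = simulate_dataset(cfg, replicate=3)
        b = simulate_dataset(cfg, replicate=3)
        assert a.counts.equals(b.counts)
        c = simulate_dataset(cfg, replicate=4)
        assert not a.counts.equals(c.counts)

    def test_labels_match_cluster_sizes(self):
        data = simulate_dataset(SimulationConfig(seed=0), replicate=0)
        _, counts = np.unique(data.true_labels, return_counts=True)
        assert tuple(counts) == DEFAULT_CLUSTER_SIZES
        values = data.counts.to_numpy()
        assert values.dtype.kind == "i" and (values >= 0).all()

    def test_independent_case_moments(self):
        """phi=0 and no rate jitter: per-time means hit lambda within 3 SE and
        between-time correlations are within 3 Monte-Carlo SEs of zero."""
        n = 10_000
        lam = (50.0, 80.0, 120.0, 60.0)
        cfg = SimulationConfig(
            cluster_sizes=(n,), lambda_profiles=(lam,), lambda_cv=0.0, phi=0.0, seed=2
        )
        counts = simulate_dataset(cfg, 0).counts.to_numpy()
        for t, l in enumerate(lam):
            se = np.sqrt(l / n)
            assert abs(counts[:, t].mean() - l) < 3 * se
        corr = np.corrcoef(counts.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n))

    def test_lag1_correlation_attenuated_copula(self):
        """phi=0.9 at lambda=50: count lag-1 correlation lands in [0.80, 0.92],
        below the Gaussian 0.9 because of the discrete marginals."""
        cfg = SimulationConfig(
            cluster_sizes=(10_000,),
            lambda_profiles=((50.0, 50.0, 50.0, 50.0),),
            lambda_cv=0.0,
            phi=0.9,
            seed=3,
        )
        counts = simulate_dataset(cfg, 0).counts.to_numpy().astype(float)
        r = _lag1_corr(counts)
        assert 0.80 <= r <= 0.92

    def test_lag1_correlation_monotone_in_phi(self):
        rs = []
        for phi in (0.0, 0.3, 0.6, 0.9):
            cfg = SimulationConfig(
                cluster_sizes=(10_000,),
                lambda_profiles=((50.0,) * 4,),
                lambda_cv=0.0,
                phi=phi,
                seed=4,
            )
            counts = simulate_dataset(cfg, 0).counts.to_numpy().astype(float)
            rs.append(_lag1_corr(counts))
        assert abs(rs[0]) < 0.03  # sign/zero at phi=0
        assert rs == sorted(rs)
        assert all(r > 0 for r in rs[1:])

    def test_negative_phi_gives_negative_dependence(self):
        cfg = SimulationConfig(
            cluster_sizes=(5_000,),
            lambda_profiles=((50.0,) * 4,),
            lambda_cv=0.0,
            phi=-0.6,
            seed=5,
        )
        counts = simulate_dataset(cfg, 0).counts.to_numpy().astype(float)
        assert _lag1_corr(counts) < -0.3


class TestEstimateAr1:
    def test_hand_worked_examples(self):
        # (1,2,3,4): numerator 1.25, denominator 5.0
        assert estimate_ar1([1.0, 2.0, 3.0, 4.0]) == pytest.approx(0.25)
        assert estimate_ar1([1.0, -1.0, 1.0, -1.0]) == pytest.approx(-0.75)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_ar1([3.0, 3.0, 3.0, 3.0])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="length >= 3"):
            estimate_ar1([1.0, 2.0])

    @pytest.mark.parametrize("phi", [0.2, 0.5, 0.8])
    def test_recovers_phi_on_long_gaussian_series(self, phi):
        rng = np.random.default_rng(10)
        n = 10_000
        e = rng.standard_normal(n)
        y = np.empty(n)
        y[0] = e[0]
        for t in range(1, n):
            y[t] = phi * y[t - 1] + np.sqrt(1 - phi**2) * e[t]
        assert estimate_ar1(y) == pytest.approx(phi, abs=0.02)


class TestCalibratePhi:
    def test_per_cluster_mean(self):
        series = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],    # phi_hat = 0.25
                [1.0, -1.0, 1.0, -1.0],  # phi_hat = -0.75
                [1.0, 2.0, 3.0, 4.0],    # phi_hat = 0.25 (cluster 2, singleton)
            ]
        )
        labels = np.array([1, 1, 2])
        phis = calibrate_phi(series, labels)
        assert phis[1] == pytest.approx((0.25 - 0.75) / 2)
        assert phis[2] == pytest.approx(0.25)

    def test_constant_genes_skipped(self):
        series = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        phis = calibrate_phi(series, np.array([1, 1]))
        assert phis[1] == pytest.approx(0.25)

    def test_cluster_of_constant_genes_rejected(self):
        series = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="2"):
            calibrate_phi(series, np.array([1, 2]))

    def test_round_trip_with_simulator(self):
        """Cluster-level estimates preserve the ordering of the generating phi
        on 4-point series (where the lag-1 estimator is strongly biased
        downward) and recover the signs once the series are longer."""
        cfg = SimulationConfig(
            cluster_sizes=(2000, 2000),
            lambda_profiles=((80.0,) * 4, (80.0,) * 4),
            lambda_cv=0.0,
            phi=(0.8, -0.5),
            seed=6,
        )
        data = simulate_dataset(cfg, 0)
        phis = calibrate_phi(data.counts.to_numpy().astype(float), data.true_labels)
        assert phis[1] > phis[2]

        cfg12 = SimulationConfig(
            cluster_sizes=(3000, 3000),
            lambda_profiles=((80.0,) * 12, (80.0,) * 12),
            lambda_cv=0.0,
            phi=(0.8, -0.5),
            seed=6,
        )
        data12 = simulate_dataset(cfg12, 0)
        phis12 = calibrate_phi(data12.counts.to_numpy().astype(float), data12.true_labels)
        assert phis12[1] > 0 > phis12[2]
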