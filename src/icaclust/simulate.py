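"""Simulation of temporally correlated RNA-seq count series.

Each gene belongs to one of K clusters; a cluster is characterised by a
length-N profile of Poisson rates (one per time point) and an AR(1)
autocorrelation parameter phi.  A gene's counts are generated by a Gaussian
copula (NORTA) construction:

1. per-gene rates lambda_t ~ Normal(lambda_tk, (cv * lambda_tk)^2), truncated
   below at 0.1, so genes within a cluster share a mean profile but differ in
   level;
2. Z ~ MVN(0, R_k) with R_k[t, t'] = phi_k^|t - t'| (first-order
   autoregressive correlation across time);
3. Y_t = F^{-1}_Poisson(Phi(Z_t); lambda_t), the Poisson quantile transform of
   the Gaussian CDF values.

The resulting counts have (approximately) Poisson marginals with the intended
rates, and serial dependence whose lag-1 correlation has the sign of phi but
is attenuated relative to the Gaussian phi by the discreteness of the
marginals; no intermediate-correlation correction is applied.

The default scenario emulates a differential-expression study of 458 genes in
6 clusters (sizes 89/51/153/67/40/58) over 4 time points, with six
qualitatively distinct temporal patterns: falling (A), early-peak (B),
uniformly high (C), rising (D), mid-peak (E) and uniformly low (F).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LAMBDA_PROFILES",
    "DEFAULT_CLUSTER_SIZES",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "estimate_ar1",
    "calibrate_phi",
]

DEFAULT_CLUSTER_SIZES = (89, 51, 153, 67, 40, 58)

DEFAULT_LAMBDA_PROFILES = (
    (150.0, 120.0, 60.0, 50.0),  # A: falling
    (200.0, 80.0, 70.0, 75.0),   # B: high early only
    (180.0, 170.0, 160.0, 150.0),  # C: uniformly high
    (50.0, 60.0, 120.0, 160.0),  # D: rising (mirror of A)
    (80.0, 85.0, 160.0, 90.0),   # E: mid/late peak
    (40.0, 45.0, 50.0, 40.0),    # F: uniformly low
)


@dataclass
class SimulationConfig:
    """Scenario description for the correlated-count simulator.

    Parameters
    ----------
    cluster_sizes : genes per cluster; the default six sizes total 458.
    lambda_profiles : per-cluster Poisson rate profile over time (reads).
    lambda_cv : coefficient of variation of the per-gene rate jitter around
        the cluster profile (sd = cv * lambda); 0.10 by default.
    phi : per-cluster AR(1) parameter in (-1, 1); a scalar is broadcast.
    n_replicates : replicate datasets per study (default 10).
    seed : master seed; together with the replicate index it fully determines
        a dataset.
    """

    cluster_sizes: tuple = DEFAULT_CLUSTER_SIZES
    lambda_profiles: tuple = DEFAULT_LAMBDA_PROFILES
    lambda_cv: float = 0.10
    phi: tuple | float = 0.5
    n_replicates: int = 10
    seed: int = 0
    rate_floor: float = 0.1

    def __post_init__(self):
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        self.lambda_profiles = tuple(tuple(float(v) for v in p) for p in self.lambda_profiles)
        if np.isscalar(self.phi):
            self.phi = tuple(float(self.phi) for _ in self.cluster_sizes)
        else:
            self.phi = tuple(float(p) for p in self.phi)
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_genes(self) -> int:
        return sum(self.cluster_sizes)

    @property
    def n_timepoints(self) -> int:
        return len(self.lambda_profiles[0])

    def validate(self) -> None:
        if len(self.lambda_profiles) != len(self.cluster_sizes):
            raise ValueError("one lambda profile required per cluster")
        if len(self.phi) != len(self.cluster_sizes):
            raise ValueError("one phi required per cluster")
        n = self.n_timepoints
        if n < 2:
            raise ValueError("need at least 2 time points")
        for k, prof in enumerate(self.lambda_profiles):
            if len(prof) != n:
                raise ValueError("all lambda profiles must share a length")
            if any(v <= 0 for v in prof):
                raise ValueError(f"lambda profile of cluster {k + 1} must be positive")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if any(not -1 < p < 1 for p in self.phi):
            raise ValueError("phi must lie in (-1, 1)")
        if self.lambda_cv < 0:
            raise ValueError("lambda_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_sizes"] = list(d["cluster_sizes"])
        d["lambda_profiles"] = [list(p) for p in d["lambda_profiles"]]
        d["phi"] = list(d["phi"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class SimulatedDataset:
    counts: pd.DataFrame            # genes x time, non-negative integers
    true_labels: np.ndarray         # cluster id (1..K) per gene
    config: SimulationConfig
    replicate: int

    @property
    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.counts.index, "cluster": self.true_labels})


def _ar1_correlation(phi: float, n: int) -> np.ndarray:
    idx = np.arange(n)
    return phi ** np.abs(idx[:, None] - idx[None, :])


def simulate_dataset(config: SimulationConfig, replicate: int = 0) -> SimulatedDataset:
    """Generate one replicate dataset; bit-identical for a fixed
    (config.seed, replicate) pair."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), int(replicate)])
    n_t = config.n_timepoints
    blocks = []
    labels = []
    for k, (size, profile, phi) in enumerate(
        zip(config.cluster_sizes, config.lambda_profiles, config.phi), start=1
    ):
        lam = np.asarray(profile)
        rates = rng.normal(loc=lam, scale=config.lambda_cv * lam, size=(size, n_t))
        np.maximum(rates, config.rate_floor, out=rates)
        corr = _ar1_correlation(phi, n_t)
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((size, n_t)) @ chol.T
        u = stats.norm.cdf(z)
        counts = stats.poisson.ppf(u, rates).astype(np.int64)
        blocks.append(counts)
        labels.extend([k] * size)
    values = np.vstack(blocks)
    gene_ids = [f"gene_{i + 1:04d}" for i in range(values.shape[0])]
    time_labels = [f"t{j + 1}" for j in range(n_t)]
    counts = pd.DataFrame(values, index=gene_ids, columns=time_labels)
    return SimulatedDataset(
        counts=counts,
        true_labels=np.asarray(labels, dtype=int),
        config=config,
        replicate=replicate,
    )


def estimate_ar1(series) -> float:
    """Lag-1 sample autocorrelation of a single series:

        phi_hat = sum_t (y_t - ybar)(y_{t+1} - ybar) / sum_t (y_t - ybar)^2
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a 1-D series of length >= 3")
    d = y - y.mean()
    denom = float(np.sum(d**2))
    if denom == 0:
        raise ValueError("constant series: lag-1 autocorrelation undefined")
    return float(np.sum(d[:-1] * d[1:]) / denom)


def calibrate_phi(series_matrix, labels) -> dict[int, float]:
    """Per-cluster mean of per-gene lag-1 autocorrelations.

    Genes whose series is constant (autocorrelation inestimable) are skipped
    with a logged count; a cluster with no estimable gene raises.  This is the
    calibration step that ties the simulator's AR(1) parameters to a real
    clustered dataset.
    """
    if isinstance(series_matrix, pd.DataFrame):
        values = series_matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(series_matrix, dtype=float)
    labels = np.asarray(labels)
    if labels.size != values.shape[0]:
        raise ValueError("one label per gene required")
    result: dict[int, float] = {}
    for k in np.unique(labels):
        rows = values[labels == k]
        estimates = []
        skipped = 0
        for row in rows:
            try:
                estimates.append(estimate_ar1(row))
            except ValueError:
                skipped += 1
        if skipped:
            logger.info("calibrate_phi: cluster %s skipped %d constant genes", k, skipped)
        if not estimates:
            raise ValueError(f"cluster {k!r} has no gene with estimable autocorrelation")
        result[int(k) if np.issubdtype(labels.dtype, np.integer) else k] = float(
            np.mean(estimates)
        )
    return result
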