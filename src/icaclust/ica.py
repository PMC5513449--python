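"""Independent component analysis of short expression time series, and
Hoeffding's D test of pairwise component independence.

The model is the classic linear mixing model Y = A S: each gene's centered
time series (a row of the m x N matrix Y) is a linear combination of N-sample
source signals that are statistically independent across genes.  Estimation
follows the standard two-stage FastICA scheme: PCA whitening (K) followed by
an orthogonal rotation (R) found by symmetric fixed-point iteration maximising
non-Gaussianity under the logcosh contrast, so that A ~ K^+ R.  Genes are
observations and time points are variables, so each gene receives a k-vector
of component scores — the features later used for clustering.

Components are identifiable only up to sign, scale and permutation; the
convention here is unit sample variance for each score column, all scale being
carried by the temporal mixing matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "ICADecomposition",
    "TemporalICA",
    "decompose",
    "hoeffding_d",
    "hoeffding_d_test",
    "independence_report",
]


@dataclass
class ICADecomposition:
    """Result of decomposing a genes x time series matrix.

    Attributes
    ----------
    scores : (m, k) array
        Per-gene coordinates on the independent components (unit sample
        variance per column).  These are the clustering features.
    mixing : (k, N) array
        Temporal signature of each component; ``scores @ mixing`` restores the
        column-centered input exactly when k = N.
    whitening : (N, k) array
        PCA whitening map: ``(Y - column_means) @ whitening`` has identity
        sample covariance.
    rotation : (k, k) orthogonal array
        The independence-maximising rotation applied after whitening.
    column_means : (N,) array
    gene_ids, time_labels : labels carried through from the input.
    converged, n_iter, final_tol : fixed-point iteration diagnostics.
    """

    scores: np.ndarray
    mixing: np.ndarray
    whitening: np.ndarray
    rotation: np.ndarray
    column_means: np.ndarray
    k: int
    converged: bool
    n_iter: int
    final_tol: float
    gene_ids: list = field(default_factory=list)
    time_labels: list = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        """Column-centered reconstruction ``scores @ mixing``."""
        return self.scores @ self.mixing

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"IC{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.scores, index=self.gene_ids, columns=cols)


def _as_matrix(series) -> tuple[np.ndarray, list, list]:
    if isinstance(series, pd.DataFrame):
        return series.to_numpy(dtype=float), list(series.index), list(series.columns)
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D genes x time matrix")
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^{-1/2} W via eigendecomposition of the (small) Gram matrix
    vals, vecs = np.linalg.eigh(W @ W.T)
    if np.min(vals) <= 0:
        raise np.linalg.LinAlgError("degenerate rotation during decorrelation")
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T @ W


class TemporalICA(TransformerMixin, BaseEstimator):
    """FastICA transformer for genes x time series matrices.

    Parameters
    ----------
    n_components : int or None
        Number of independent components k; ``None`` keeps the full dimension
        (k = number of time points), the recommended choice for short series
        where no information should be discarded.
    max_iter : int
        Cap on symmetric fixed-point iterations.
    tol : float
        Convergence tolerance on the rotation update (max over components of
        ``|1 - |<w_new, w_old>||``).
    random_state : int or None
        Seed for the random orthogonal initialisation of the rotation.

    Attributes (after fit)
    ----------------------
    decomposition_ : ICADecomposition
    scores_ : (m, k) ndarray — alias of ``decomposition_.scores``
    mixing_ : (k, N) ndarray
    whitening_ : (N, k) ndarray
    rotation_ : (k, k) ndarray
    mean_ : (N,) ndarray
    """

    def __init__(
        self,
        n_components: int | None = None,
        max_iter: int = 200,
        tol: float = 1e-4,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        Y, gene_ids, time_labels = _as_matrix(X)
        m, N = Y.shape
        k = N if self.n_components is None else int(self.n_components)
        if not 1 <= k <= min(m, N):
            raise ValueError(f"n_components must be in [1, min(m, N)] = [1, {min(m, N)}]")
        if m < 2:
            raise ValueError("need at least 2 series (genes)")

        means = Y.mean(axis=0)
        Yc = Y - means

        variances = Yc.var(axis=0, ddof=1)
        if np.any(variances <= 0):
            col = time_labels[int(np.argmin(variances))]
            raise ValueError(f"time column {col!r} has zero variance after centering")

        # PCA whitening: Z = Yc K with unit sample covariance (ddof=1)
        cov = (Yc.T @ Yc) / (m - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:k]
        evals, evecs = evals[order], evecs[:, order]
        if np.min(evals) <= max(1e-12 * np.max(evals), 0.0):
            raise ValueError(
                "series matrix is rank-deficient; reduce n_components below "
                f"{k}"
            )
        K = evecs / np.sqrt(evals)
        Z = Yc @ K

        rng = np.random.default_rng(self.random_state)
        # rotation columns are the component directions in whitened space
        R = _sym_decorrelate(rng.standard_normal((k, k))).T

        converged = False
        change = np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            U = Z @ R
            G = np.tanh(U)
            g_prime = 1.0 - G**2
            R_new = (Z.T @ G) / m - R * g_prime.mean(axis=0)
            R_new = _sym_decorrelate(R_new.T).T
            change = float(np.max(np.abs(np.abs(np.sum(R_new * R, axis=0)) - 1.0)))
            R = R_new
            if change < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"FastICA did not converge in {self.max_iter} iterations "
                f"(last change {change:.2e}); results may be unstable",
                RuntimeWarning,
            )

        scores = Z @ R
        # deterministic orientation: largest-magnitude mixing entry positive
        mixing = R.T @ np.linalg.pinv(K)
        signs = np.sign(mixing[np.arange(k), np.argmax(np.abs(mixing), axis=1)])
        signs[signs == 0] = 1.0
        scores = scores * signs
        mixing = mixing * signs[:, None]
        R = R * signs

        self.decomposition_ = ICADecomposition(
            scores=scores,
            mixing=mixing,
            whitening=K,
            rotation=R,
            column_means=means,
            k=k,
            converged=converged,
            n_iter=it,
            final_tol=change,
            gene_ids=gene_ids,
            time_labels=time_labels,
        )
        self.scores_ = scores
        self.mixing_ = mixing
        self.whitening_ = K
        self.rotation_ = R
        self.mean_ = means
        self.n_features_in_ = N
        return self

    def transform(self, X):
        check_is_fitted(self, "scores_")
        Y, _, _ = _as_matrix(X)
        return (Y - self.mean_) @ self.whitening_ @ self.rotation_

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_


def decompose(
    series,
    k: int | None = None,
    seed: int | None = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> ICADecomposition:
    """Functional wrapper around :class:`TemporalICA`."""
    est = TemporalICA(n_components=k, max_iter=max_iter, tol=tol, random_state=seed)
    return est.fit(series).decomposition_


# ---------------------------------------------------------------------------
# Hoeffding's D
# ---------------------------------------------------------------------------


def _bivariate_ranks(cx_lt: np.ndarray, cx_eq: np.ndarray, cy_lt: np.ndarray, cy_eq: np.ndarray) -> np.ndarray:
    # Q_i = 1 + #{j : x_j < x_i, y_j < y_i}, ties counted fractionally
    # (1/2 per single tie, 1/4 per double tie, self excluded)
    q = (
        (cx_lt & cy_lt).sum(axis=0)
        + 0.5 * ((cx_eq & cy_lt).sum(axis=0) + (cx_lt & cy_eq).sum(axis=0))
        + 0.25 * ((cx_eq & cy_eq).sum(axis=0) - 1)  # subtract self
    )
    return 1.0 + q


def hoeffding_d(x, y) -> float:
    """Hoeffding's (1948) rank statistic D for dependence between two samples.

    D measures the distance between the empirical joint CDF and the product of
    the empirical marginals; it is ~0 under independence and is scaled to the
    conventional range [-0.5, 1].  Requires n >= 5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if n < 5:
        raise ValueError("Hoeffding's D requires n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: all values tied")

    r = rankdata(x)
    s = rankdata(y)
    cx_lt = x[:, None] < x[None, :]
    cx_eq = x[:, None] == x[None, :]
    cy_lt = y[:, None] < y[None, :]
    cy_eq = y[:, None] == y[None, :]
    q = _bivariate_ranks(cx_lt, cx_eq, cy_lt, cy_eq)

    d1 = np.sum((q - 1.0) * (q - 2.0))
    d2 = np.sum((r - 1.0) * (r - 2.0) * (s - 1.0) * (s - 2.0))
    d3 = np.sum((r - 2.0) * (s - 2.0) * (q - 1.0))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return float(30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom)


def hoeffding_d_test(
    x, y, n_permutations: int = 1000, seed: int | None = 0
) -> tuple[float, float]:
    """Hoeffding's D with a permutation p-value.

    The null distribution is generated by randomly permuting ``y``;
    ``p = (1 + #{D* >= D}) / (1 + n_permutations)``, so the smallest
    attainable p-value is 1/(n_permutations + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d_obs = hoeffding_d(x, y)
    n = x.size

    r = rankdata(x)
    s = rankdata(y)
    cx_lt = x[:, None] < x[None, :]
    cx_eq = x[:, None] == x[None, :]
    cy_lt = y[:, None] < y[None, :]
    cy_eq = y[:, None] == y[None, :]
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)

    def _d_from_parts(r_, s_, cyl, cye) -> float:
        q = _bivariate_ranks(cx_lt, cx_eq, cyl, cye)
        d1 = np.sum((q - 1.0) * (q - 2.0))
        d2 = np.sum((r_ - 1.0) * (r_ - 2.0) * (s_ - 1.0) * (s_ - 2.0))
        d3 = np.sum((r_ - 2.0) * (s_ - 2.0) * (q - 1.0))
        return float(30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        d_star = _d_from_parts(r, s[perm], cy_lt[np.ix_(perm, perm)], cy_eq[np.ix_(perm, perm)])
        if d_star >= d_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return d_obs, p


def independence_report(
    dec: ICADecomposition, n_permutations: int = 1000, seed: int | None = 0
) -> pd.DataFrame:
    """Hoeffding's D test for every unordered pair of component score columns.

    Returns a tidy frame with one row per pair (k(k-1)/2 rows) and columns
    ``component_a, component_b, D, p_value``.  Used to verify that the
    recovered components are, as intended, statistically independent.
    """
    k = dec.k
    if k < 2:
        raise ValueError("independence report needs at least 2 components")
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            d, p = hoeffding_d_test(
                dec.scores[:, a],
                dec.scores[:, b],
                n_permutations=n_permutations,
                seed=None if seed is None else seed + 1000 * a + b,
            )
            rows.append({"component_a": a + 1, "component_b": b + 1, "D": d, "p_value": p})
    report = pd.DataFrame(rows)
    report.attrs["n_permutations"] = n_permutations
    report.attrs["seed"] = seed
    return report
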