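"""Clustering evaluation by correct classification rate (CCR) and the
method-comparison experiment grids.

CCR is the fraction of genes assigned to their true cluster after predicted
cluster labels have been matched one-to-one to true labels so as to maximise
the number of agreements (optimal assignment on the confusion matrix).  Genes
in predicted clusters left unmatched (when the predicted and true cluster
counts differ) count as errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cluster import ICAClust, cut_dendrogram, kmeans_baseline, mojena_select
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "CCRResult",
    "ComparisonGrid",
    "ccr",
    "run_comparison",
    "summarize_modal_k",
    "DEFAULT_K_GRID",
    "DEFAULT_C_GRID",
]

DEFAULT_K_GRID = (2, 3, 4, 5, 6, 7)
DEFAULT_C_GRID = (2.25, 2.50, 2.75, 3.00, 3.25, 3.50, 3.75)


@dataclass
class CCRResult:
    ccr: float                     # fraction in [0, 1]
    confusion: pd.DataFrame        # true x predicted counts
    mapping: dict                  # predicted label -> true label

    @property
    def percent(self) -> float:
        return 100.0 * self.ccr


@dataclass
class ComparisonGrid:
    """Tidy per-run results and per-setting summaries of a method comparison.

    ``rows`` has one record per (method, setting, replicate) with the CCR and,
    for the two-step method, the automatically selected cluster count;
    ``summary`` aggregates mean and SD of CCR per (method, setting).
    """

    rows: pd.DataFrame
    summary: pd.DataFrame


def ccr(truth, predicted) -> CCRResult:
    """Correct classification rate with optimal one-to-one label matching."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValueError("truth and predicted must be 1-D label vectors of equal length")
    n = truth.size
    if n == 0:
        raise ValueError("empty label vectors")
    t_labels, t_idx = np.unique(truth, return_inverse=True)
    p_labels, p_idx = np.unique(predicted, return_inverse=True)
    confusion = np.zeros((t_labels.size, p_labels.size), dtype=int)
    np.add.at(confusion, (t_idx, p_idx), 1)
    row_ind, col_ind = linear_sum_assignment(confusion, maximize=True)
    matched = int(confusion[row_ind, col_ind].sum())
    mapping = {p_labels[c]: t_labels[r] for r, c in zip(row_ind, col_ind)}
    frame = pd.DataFrame(confusion, index=t_labels, columns=p_labels)
    frame.index.name = "true"
    frame.columns.name = "predicted"
    return CCRResult(ccr=matched / n, confusion=frame, mapping=mapping)


def run_comparison(
    config: SimulationConfig,
    k_grid=DEFAULT_K_GRID,
    c_grid=DEFAULT_C_GRID,
    seed: int | None = None,
    n_replicates: int | None = None,
) -> ComparisonGrid:
    """Simulate replicate datasets and score both methods on each.

    For every replicate the same simulated dataset is analysed by k-means at
    every k in ``k_grid`` (on the raw count matrix) and by the two-step method
    at every Mojena constant in ``c_grid``.  CCR is computed against the
    simulation truth with optimal matching.

    ``seed`` overrides ``config.seed`` as the master seed; all randomness
    (simulation, ICA initialisation, k-means initialisation) derives from it.
    """
    k_grid = tuple(k_grid)
    c_grid = tuple(c_grid)
    if not k_grid and not c_grid:
        raise ValueError("at least one of k_grid / c_grid must be nonempty")
    if seed is not None:
        config = SimulationConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    master = int(config.seed)
    n_rep = config.n_replicates if n_replicates is None else int(n_replicates)

    records = []
    for rep in range(n_rep):
        data = simulate_dataset(config, replicate=rep)
        # independent per-purpose substreams derived from the master seed
        ica_seed = (master * 1009 + 2 * rep + 1) % (2**31 - 1)
        km_seed = (master * 1013 + 2 * rep) % (2**31 - 1)
        for k in k_grid:
            pred = kmeans_baseline(data.counts, k=k, seed=km_seed)
            res = ccr(data.true_labels, pred)
            records.append(
                {
                    "method": "kmeans",
                    "setting": float(k),
                    "replicate": rep,
                    "ccr": res.ccr,
                    "selected_k": k,
                }
            )
        if c_grid:
            model = ICAClust(c=c_grid[0], random_state=ica_seed).fit(data.counts)
            for c in c_grid:
                # the decomposition and dendrogram do not depend on c; only
                # the Mojena cut does, so reuse them across the c grid
                moj = mojena_select(model.dendrogram_, c=c)
                labels = cut_dendrogram(model.dendrogram_, moj.selected_k)
                res = ccr(data.true_labels, labels)
                records.append(
                    {
                        "method": "icaclust",
                        "setting": float(c),
                        "replicate": rep,
                        "ccr": res.ccr,
                        "selected_k": moj.selected_k,
                    }
                )
    rows = pd.DataFrame.from_records(records)
    summary = (
        rows.groupby(["method", "setting"])["ccr"]
        .agg(mean_ccr="mean", sd_ccr=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    return ComparisonGrid(rows=rows, summary=summary)


def summarize_modal_k(grid: ComparisonGrid) -> int:
    """Mode of the automatically selected cluster count across all two-step
    runs (every replicate and every Mojena constant); ties broken toward the
    smaller count."""
    sel = grid.rows.loc[grid.rows["method"] == "icaclust", "selected_k"]
    if sel.empty:
        raise ValueError("comparison grid contains no two-step (icaclust) rows")
    counts = sel.value_counts()
    best = counts.max()
    return int(min(k for k, v in counts.items() if v == best))
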