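"""Replicated train/candidate experiments and accuracy summaries.

Runs GBLUP and/or RHEPCG over replicated F2 simulations (or user-supplied
splits), scores candidate predictions by the squared Pearson correlation
between candidate phenotypes and predicted genotypic values, and reports
per-replicate rows plus mean +/- standard-error summaries per method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .estimators import GBLUPRegressor, RHEPCGRegressor
from .simulate import SimulationConfig, simulate_population, substream

__all__ = [
    "ExperimentSummary",
    "accuracy_r2",
    "run_experiment",
    "heritability_accuracy_correlation",
]


def accuracy_r2(y_cand: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between candidate phenotypes and
    predicted genotypic values — the prediction-accuracy metric.

    Invariant to affine rescaling of either argument; both vectors must be
    non-constant with length >= 3.
    """
    y_cand = np.asarray(y_cand, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if y_cand.shape != predicted.shape or y_cand.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if y_cand.size < 3:
        raise ValueError("need at least 3 candidates")
    if np.ptp(y_cand) == 0 or np.ptp(predicted) == 0:
        raise ValueError("correlation undefined for a constant vector")
    c = float(np.corrcoef(y_cand, predicted)[0, 1])
    return c * c


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-replicate results and mean +/- SE summary of one scenario.

    SE is the sample standard deviation across replicates (divisor
    reps - 1) over sqrt(reps); absent (NaN) with a single replicate.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    config: SimulationConfig


def _fit_one(method: str, Xt, yt, Xc, seed: int):
    if method == "RHEPCG":
        model = RHEPCGRegressor(random_state=seed).fit(Xt, yt)
        extra = {"iterations": model.n_iter_}
    elif method == "GBLUP":
        model = GBLUPRegressor().fit(Xt, yt)
        extra = {"iterations": np.nan}
    else:
        raise ValueError(f"unknown method {method!r}")
    return model.h2_, model.predict(Xc), extra


def run_experiment(
    config: SimulationConfig,
    methods: Iterable[str] = ("GBLUP", "RHEPCG"),
    *,
    replications: Optional[int] = None,
) -> ExperimentSummary:
    """Simulate ``replications`` F2 cohorts and score each method on each.

    Replicate r is seeded ``config.seed + r`` so scenarios are reproducible
    and replicate order cannot matter.  Any replicate failure aborts with
    the replicate index and cause.
    """
    methods = list(methods)
    reps = config.replications if replications is None else int(replications)
    rows = []
    for r in range(reps):
        seed_r = config.replicate_seed(r)
        try:
            pop = simulate_population(config, rng=substream(seed_r, "simulate"))
            Xt = pop.genotypes.matrix[pop.train_idx].astype(float)
            yt = pop.phenotypes[pop.train_idx]
            Xc = pop.genotypes.matrix[pop.cand_idx].astype(float)
            yc = pop.phenotypes[pop.cand_idx]
            gc = pop.g_true[pop.cand_idx]
            for method in methods:
                h2_hat, pred, extra = _fit_one(method, Xt, yt, Xc, seed_r)
                rows.append(
                    {
                        "replicate": r,
                        "method": method,
                        "h2_hat": h2_hat,
                        "r2": accuracy_r2(yc, pred),
                        # supplementary, less noisy accuracy vs true genetic values
                        "r2_vs_g": accuracy_r2(gc, pred),
                        **extra,
                    }
                )
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"replicate {r} (seed {seed_r}) failed: {exc}") from exc

    per_rep = pd.DataFrame(rows)
    agg = per_rep.groupby("method", sort=True)
    summary = pd.DataFrame(
        {
            "mean_h2": agg["h2_hat"].mean(),
            "se_h2": agg["h2_hat"].apply(_se),
            "mean_r2": agg["r2"].mean(),
            "se_r2": agg["r2"].apply(_se),
            "mean_r2_vs_g": agg["r2_vs_g"].mean(),
            "replications": agg.size(),
        }
    )
    return ExperimentSummary(per_replicate=per_rep, summary=summary, config=config)


def _se(x: pd.Series) -> float:
    x = x.to_numpy(dtype=float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def heritability_accuracy_correlation(
    h2_means: np.ndarray, r2_means: np.ndarray
) -> float:
    """Pearson correlation of mean estimated heritability vs mean accuracy
    across heritability levels (needs at least 3 pairs)."""
    h2_means = np.asarray(h2_means, dtype=float)
    r2_means = np.asarray(r2_means, dtype=float)
    if h2_means.size < 3 or h2_means.shape != r2_means.shape:
        raise ValueError("need at least 3 (h2, r2) pairs of equal length")
    return float(np.corrcoef(h2_means, r2_means)[0, 1])
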