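"""F2 population simulator for genomic-prediction benchmarking.

A single chromosome of length 2,000 cM carries m equally spaced markers;
adjacent markers recombine with constant fraction c (a first-order Markov
chain along the chromosome, no interference).  Every marker is a QTL with
an i.i.d. standard-normal effect.  Each F2 individual is the sum of two
independent gametes, so allele dosages are {0, 1, 2} with expected
genotype frequencies 1/4 : 1/2 : 1/4 and allele frequency 1/2 at every
marker.

Genetic values are computed on the centered/scaled design built from the
whole simulated cohort so that the simulated additive variance lives on
the same GRM scale the estimators report; the residual variance is
calibrated to the empirical variance of the genetic values so that the
realized heritability matches the target in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import zlib

import numpy as np

from .core import RawGenotypes, standardize

__all__ = [
    "SimulationConfig",
    "F2Population",
    "simulate_gamete",
    "simulate_gametes",
    "simulate_population",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream fanned out from one global seed.

    Keeps stages independent: toggling e.g. the trace-probe draws does not
    perturb the simulation draws.
    """
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation scenario.

    ``n_markers`` defaults to 2,000: with a 2,000 cM chromosome and c = 0.01
    between neighbours that is one marker per centimorgan (at 1 cM the map
    distance and recombination fraction agree to first order).
    """

    n_train: int
    n_cand: int
    h2: float
    c: float = 0.01
    chrom_length_cM: float = 2000.0
    n_markers: int = 2000
    seed: int = 0
    replications: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.c < 0.5):
            raise ValueError("recombination fraction c must lie in (0, 0.5)")
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must lie in (0, 1)")
        if self.n_train < 2:
            raise ValueError("n_train must be >= 2")
        if self.n_cand < 1:
            raise ValueError("n_cand must be >= 1")
        if self.n_markers < 2:
            raise ValueError("n_markers must be >= 2")

    def replicate_seed(self, r: int) -> int:
        """Seed of replicate r (0-based): base seed + r."""
        return int(self.seed) + int(r)


@dataclass(frozen=True)
class F2Population:
    """One simulated F2 cohort with its generating truth."""

    genotypes: RawGenotypes
    beta_true: np.ndarray
    g_true: np.ndarray
    phenotypes: np.ndarray
    train_idx: np.ndarray
    cand_idx: np.ndarray
    sigma_e2_used: float
    config: SimulationConfig = field(repr=False, default=None)


def simulate_gametes(
    n_gametes: int, m: int, c: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw gametes as first-order Markov chains along the chromosome.

    The allele at the first marker is Bernoulli(1/2); the allele at marker
    i+1 differs from the allele at marker i with probability exactly c.
    Returns a (n_gametes, m) uint8 array of parental origins (0/1).
    """
    if not (0.0 <= c < 0.5):
        raise ValueError("recombination fraction c must lie in [0, 0.5)")
    first = rng.random(n_gametes) < 0.5
    switches = rng.random((n_gametes, m - 1)) < c
    # cumulative XOR: an odd number of switches up to an interval flips the allele
    state = np.empty((n_gametes, m), dtype=np.uint8)
    state[:, 0] = first
    cum = np.cumsum(switches, axis=1) & 1
    state[:, 1:] = np.bitwise_xor(first[:, None].astype(np.uint8), cum.astype(np.uint8))
    return state


def simulate_gamete(m: int, c: float, rng: np.random.Generator) -> np.ndarray:
    """Single-gamete convenience wrapper around :func:`simulate_gametes`."""
    return simulate_gametes(1, m, c, rng)[0]


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> F2Population:
    """Simulate one F2 replicate under ``config``.

    Draw order from a single stream (gametes, marker effects, noise) is
    fixed for reproducibility; an identical seed and config gives a
    bit-identical population.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = substream(config.seed if rng is None else int(rng), "simulate")
    n = config.n_train + config.n_cand
    m = config.n_markers

    for _attempt in range(10):
        gam_a = simulate_gametes(n, m, config.c, rng)
        gam_b = simulate_gametes(n, m, config.c, rng)
        dosages = (gam_a + gam_b).astype(np.int8)
        poly = dosages.min(axis=0) != dosages.max(axis=0)
        if poly.all():
            break
        # vanishing probability at realistic sizes; redraw the cohort
    else:
        raise RuntimeError("could not simulate a fully polymorphic cohort")

    raw = RawGenotypes(matrix=dosages)
    beta = rng.standard_normal(m)

    design = standardize(raw)  # cohort-scale centered/scaled design
    g = design.Z @ beta
    var_g = float(np.var(g, ddof=1))
    sigma_e2 = var_g * (1.0 - config.h2) / config.h2
    e = rng.standard_normal(n) * np.sqrt(sigma_e2)
    phenotypes = g + e

    idx = np.arange(n)
    return F2Population(
        genotypes=raw,
        beta_true=beta,
        g_true=g,
        phenotypes=phenotypes,
        train_idx=idx[: config.n_train],
        cand_idx=idx[config.n_train :],
        sigma_e2_used=sigma_e2,
        config=config,
    )
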