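"""MCMC configuration, state and chain containers for the two-population
latent-variable SNP-BLUP samplers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["McmcConfig", "LatentState", "ModelData", "PosteriorChain",
           "retained_cycle_count"]


def retained_cycle_count(n_cycles: int, burn_in: int, thin: int) -> int:
    """Number of post-burn-in samples kept at the given thinning interval.

    Cycles are numbered 1..n_cycles; cycle c is retained when c > burn_in
    and (c - burn_in) is a multiple of thin.
    """
    if burn_in >= n_cycles:
        raise ValueError("burn_in must be smaller than n_cycles")
    if thin < 1:
        raise ValueError("thinning interval must be >= 1")
    return (n_cycles - burn_in) // thin


@dataclass
class McmcConfig:
    """Gibbs-sampler settings.

    ``var_ceiling_factor`` scales the phenotypic variance into the upper
    bound of the flat variance priors (divergence guard).  ``start_r``
    optionally fixes the sign/magnitude of the shared-channel scalars'
    start values (useful for mirrored-initialization checks).
    """

    n_cycles: int = 50_000
    burn_in: int = 20_000
    thin: int = 20
    seed: int = 0
    store_every: int = 1
    var_ceiling_factor: float = 1e6
    start_r: tuple | None = None

    def __post_init__(self) -> None:
        retained_cycle_count(self.n_cycles, self.burn_in, self.thin)
        if self.store_every < 1:
            raise ValueError("store_every must be >= 1")
        if self.thin % self.store_every != 0:
            raise ValueError("thin must be a multiple of store_every")
        if self.burn_in % self.store_every != 0:
            raise ValueError("burn_in must be a multiple of store_every")

    @property
    def n_retained(self) -> int:
        return retained_cycle_count(self.n_cycles, self.burn_in, self.thin)


@dataclass
class ModelData:
    """Prepared sampler input: centered covariates, phenotypes, weights.

    ``weight`` entries are 1/d (record precisions up to sigma2_e); ``W``
    matrices are allele-frequency centered and share one marker map.
    """

    W1: np.ndarray
    W2: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    d1: np.ndarray
    d2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("W1", "W2", "y1", "y2", "d1", "d2"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name),
                                                     dtype=np.float64))
        if self.W1.shape[1] != self.W2.shape[1]:
            raise ValueError("panels must share one marker map")
        if len(self.y1) != self.W1.shape[0] or len(self.y2) != self.W2.shape[0]:
            raise ValueError("phenotype length != genotype rows")
        if np.any(self.d1 <= 0) or np.any(self.d2 <= 0):
            raise ValueError("residual weights must be positive")

    @property
    def n_markers(self) -> int:
        return self.W1.shape[1]


@dataclass
class LatentState:
    """One state of the hierarchical model.

    The homogeneous model is the special case with ``s1`` absent and all
    region scalars ``r_j`` zero.
    """

    u: np.ndarray                  # (2,) overall means
    s0: np.ndarray                 # (m,) shared latent vector
    r: np.ndarray                  # (2,) population-level scalars
    a_star: np.ndarray             # (m, 2) residual SNP effects
    sigma2_astar: np.ndarray       # (2,)
    sigma2_e: np.ndarray           # (2,)
    s1: np.ndarray | None = None   # (m,) region-channel latent vector
    r_j: np.ndarray | None = None  # (n_regions, 2) region scalars
    sigma2_r: np.ndarray | None = None  # (2,)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma2_astar) <= 0) or np.any(
            np.asarray(self.sigma2_e) <= 0
        ):
            raise ValueError("variances must be positive")

    def snp_effects(self, partition=None) -> np.ndarray:
        """Implied per-SNP effects a_ij = r_i s0 + r_ij s1 + a*_ij, shape (m, 2)."""
        a = self.r[np.newaxis, :] * self.s0[:, np.newaxis] + self.a_star
        if self.s1 is not None and self.r_j is not None:
            if partition is None:
                raise ValueError("partition required to expand region scalars")
            for j, reg in enumerate(partition.regions):
                sl = reg.slice()
                a[sl] += self.r_j[j][np.newaxis, :] * self.s1[sl, np.newaxis]
        return a


class PosteriorChain:
    """Stored Gibbs samples plus the bookkeeping needed for summaries.

    ``samples`` maps names to arrays whose first axis indexes stored
    cycles (every ``store_every``-th cycle of the run); burn-in and
    thinning are applied post hoc by :meth:`retained`.
    """

    def __init__(self, model, config, partition, samples, cycles,
                 ghat, u_mean, sigma2_e_mean, data):
        self.model = model
        self.config = config
        self.partition = partition
        self.samples = samples
        self.cycles = np.asarray(cycles, dtype=np.int64)
        self.ghat = ghat                      # (g1_bar, g2_bar) posterior means
        self.u_mean = np.asarray(u_mean, dtype=np.float64)
        self.sigma2_e_mean = np.asarray(sigma2_e_mean, dtype=np.float64)
        self.data = data

    # -- retention ---------------------------------------------------------

    def retained_mask(self) -> np.ndarray:
        c = self.cycles
        cfg = self.config
        return (c > cfg.burn_in) & ((c - cfg.burn_in) % cfg.thin == 0)

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask().sum())

    def retained(self) -> dict:
        mask = self.retained_mask()
        return {k: v[mask] for k, v in self.samples.items()}

    # -- deviance ----------------------------------------------------------

    def deviance_at_posterior_mean(self) -> float:
        """Deviance at the posterior mean of means, genetic values and
        residual variances (the DIC plug-in point)."""
        dev = 0.0
        for i, (y, d, g) in enumerate(
            ((self.data.y1, self.data.d1, self.ghat[0]),
             (self.data.y2, self.data.d2, self.ghat[1]))
        ):
            e = y - self.u_mean[i] - g
            s2 = self.sigma2_e_mean[i]
            dev += (len(y) * np.log(2.0 * np.pi * s2) + np.sum(np.log(d))
                    + np.sum(e * e / d) / s2)
        return float(dev)

    # -- export ------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Scalar traces as a tidy table keyed by cycle (stored cycles)."""
        cols = {"cycle": self.cycles}
        for name in ("u", "r", "sigma2_astar", "sigma2_e", "sigma2_r"):
            if name in self.samples:
                arr = self.samples[name]
                for i in range(arr.shape[1]):
                    cols[f"{name}_{i + 1}"] = arr[:, i]
        cols["deviance"] = self.samples["deviance"]
        return pd.DataFrame(cols)
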