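"""User-facing Gibbs samplers for the two-population models."""

from __future__ import annotations

import numpy as np

from ..genome_data import (
    GenotypePanel,
    RegionPartition,
    align_phenotypes,
    center_genotypes,
    partition_regions,
)
from .chain import LatentState, McmcConfig, ModelData, PosteriorChain
from . import kernels

__all__ = ["gibbs_homogeneous", "gibbs_heterogeneous", "sample_deviance",
           "prepare_model_data"]


def prepare_model_data(panels, drp_tables) -> ModelData:
    """Center genotypes and align phenotypes/weights to panel row order."""
    panel1, panel2 = panels
    if panel1.n_markers != panel2.n_markers or not np.array_equal(
        panel1.map.marker_id, panel2.map.marker_id
    ):
        raise ValueError("panels must be harmonized to one shared marker map")
    y1, d1 = align_phenotypes(panel1, drp_tables[0])
    y2, d2 = align_phenotypes(panel2, drp_tables[1])
    return ModelData(
        W1=center_genotypes(panel1),
        W2=center_genotypes(panel2),
        y1=y1, y2=y2, d1=d1, d2=d2,
    )


def _starts(data: ModelData, panels, mcmc: McmcConfig):
    vary = np.array([np.var(data.y1), np.var(data.y2)])
    sum2pq = np.array(
        [np.sum(2 * p.allele_freq * (1 - p.allele_freq)) for p in panels]
    )
    s2a_init = 0.5 * vary / np.maximum(sum2pq, 1e-12)
    if mcmc.start_r is not None:
        r_init = np.asarray(mcmc.start_r, dtype=np.float64)
    else:
        r_init = np.sqrt(s2a_init)
    ceilings = mcmc.var_ceiling_factor * np.maximum(vary, 1e-12)
    return r_init, s2a_init, ceilings


def _raise_if_diverged(status, bad_cycle, ceilings):
    if status != 0:
        raise RuntimeError(
            f"sampler diverged at cycle {bad_cycle}: a variance exceeded its "
            f"ceiling ({ceilings[0]:.3g}, {ceilings[1]:.3g}); check data scale "
            "or raise var_ceiling_factor"
        )


def gibbs_homogeneous(panels, drp_tables, mcmc: McmcConfig) -> PosteriorChain:
    """Sample the homogeneous model (one genome-wide variance channel).

    Per draw the implied per-SNP variance is r_i^2 + sigma2_a*_i and the
    cross-population covariance r_1 * r_2.
    """
    data = prepare_model_data(panels, drp_tables)
    r_init, s2a_init, ceilings = _starts(data, panels, mcmc)
    out = kernels.run_hom(
        data.W1, data.W2, data.y1, data.y2, 1.0 / data.d1, 1.0 / data.d2,
        mcmc.n_cycles, mcmc.burn_in, mcmc.store_every, mcmc.seed,
        r_init[0], r_init[1], s2a_init[0], s2a_init[1],
        ceilings[0], ceilings[1],
    )
    (status, bad_cycle, n_stored, cyc, u, r, s2a, s2e, dev, var_a, cov_a,
     ghat1, ghat2, u_mean, s2e_mean) = out
    _raise_if_diverged(status, bad_cycle, ceilings)
    sl = slice(0, n_stored)
    samples = {
        "u": u[sl], "r": r[sl], "sigma2_astar": s2a[sl], "sigma2_e": s2e[sl],
        "deviance": dev[sl], "var_a": var_a[sl], "cov_a": cov_a[sl],
    }
    partition = partition_regions(panels[0].map, "all_snp")
    return PosteriorChain(
        "homogeneous", mcmc, partition, samples, cyc[sl],
        (ghat1, ghat2), u_mean, s2e_mean, data,
    )


def gibbs_heterogeneous(
    panels, drp_tables, partition: RegionPartition, mcmc: McmcConfig
) -> PosteriorChain:
    """Sample the heterogeneous model (region-specific variance channels).

    Per draw and region j the implied per-SNP variance is
    r_i^2 + r_ij^2 + sigma2_a*_i and the covariance r_1 r_2 + r_1j r_2j.
    With a single region the model reduces to the homogeneous one plus a
    redundant channel.
    """
    data = prepare_model_data(panels, drp_tables)
    if len(partition) < 1:
        raise ValueError("partition must contain at least one region")
    if partition.n_markers != data.n_markers:
        raise ValueError("partition does not match the panels' marker map")
    for reg in partition.regions:
        if reg.n_markers < 1:
            raise ValueError(f"region {reg.index} is empty")
    rstart, rend = partition.bounds()
    r_init, s2a_init, ceilings = _starts(data, panels, mcmc)
    out = kernels.run_het(
        data.W1, data.W2, data.y1, data.y2, 1.0 / data.d1, 1.0 / data.d2,
        rstart, rend,
        mcmc.n_cycles, mcmc.burn_in, mcmc.store_every, mcmc.seed,
        r_init[0], r_init[1], s2a_init[0], s2a_init[1],
        ceilings[0], ceilings[1],
    )
    (status, bad_cycle, n_stored, cyc, u, r, rj, s2r, s2a, s2e, dev,
     var_a, cov_a, ghat1, ghat2, u_mean, s2e_mean) = out
    _raise_if_diverged(status, bad_cycle, ceilings)
    sl = slice(0, n_stored)
    samples = {
        "u": u[sl], "r": r[sl], "r_j": rj[sl], "sigma2_r": s2r[sl],
        "sigma2_astar": s2a[sl], "sigma2_e": s2e[sl], "deviance": dev[sl],
        "var_a": var_a[sl], "cov_a": cov_a[sl],
    }
    return PosteriorChain(
        "heterogeneous", mcmc, partition, samples, cyc[sl],
        (ghat1, ghat2), u_mean, s2e_mean, data,
    )


def sample_deviance(state: LatentState, data: ModelData, partition=None) -> float:
    """-2 log likelihood of the DRP given the state's means, SNP effects and
    residual variances, with record weights d."""
    a = state.snp_effects(partition)
    dev = 0.0
    for i, (y, W, d) in enumerate(
        ((data.y1, data.W1, data.d1), (data.y2, data.W2, data.d2))
    ):
        e = y - state.u[i] - W @ a[:, i]
        s2 = float(state.sigma2_e[i])
        dev += (len(y) * np.log(2.0 * np.pi * s2) + np.sum(np.log(d))
                + np.sum(e * e / d) / s2)
    return float(dev)
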