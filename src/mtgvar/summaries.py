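"""Posterior summaries: regional variance/covariance/correlation, totals,
heritability-type ratios and DIC.

Per-region genomic variance for population i is the frequency-weighted sum
sum_k 2 p_ik (1 - p_ik) * var(a_ij) over the region's markers; the
cross-population covariance uses the geometric-mean frequency weight
2 sqrt(p_1k q_1k p_2k q_2k).  Totals are plain sums over regions (between-
region covariance is deliberately ignored).  The point summary of every
posterior functional is the median; its dispersion (reported as SE) is the
posterior standard deviation; means are stored as well.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "region_variance_sum",
    "region_covariance_sum",
    "region_correlation",
    "compute_dic",
    "totals_and_h2",
    "RegionGenomicParams",
    "ModelFitReport",
    "summarize_chain",
]

#: relative floor under which a draw's region variance is treated as zero
#: for correlation purposes (the draw is excluded, with a count reported)
CORR_FLOOR_FACTOR = 1e-12


def region_variance_sum(freqs: np.ndarray, var_a) -> np.ndarray:
    """sum_k 2 p_k (1 - p_k) * var(a) over a region's markers.

    ``var_a`` may be a scalar (one draw) or an array of draws; the
    frequency weight is shared across draws.
    """
    p = np.asarray(freqs, dtype=np.float64)
    weight = np.sum(2.0 * p * (1.0 - p))
    return weight * np.asarray(var_a, dtype=np.float64)


def region_covariance_sum(freqs1: np.ndarray, freqs2: np.ndarray, cov_a) -> np.ndarray:
    """sum_k 2 sqrt(p_1k q_1k p_2k q_2k) * cov(a_1, a_2) over a region."""
    p1 = np.asarray(freqs1, dtype=np.float64)
    p2 = np.asarray(freqs2, dtype=np.float64)
    weight = np.sum(2.0 * np.sqrt(p1 * (1.0 - p1) * p2 * (1.0 - p2)))
    return weight * np.asarray(cov_a, dtype=np.float64)


def region_correlation(v1, v2, cov, floor: float = 0.0):
    """R = cov / sqrt(v1 v2); draws with a variance at or below ``floor``
    come back NaN (undefined) rather than +-inf."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    cov = np.asarray(cov, dtype=np.float64)
    valid = (v1 > floor) & (v2 > floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(valid, cov / np.sqrt(np.where(valid, v1 * v2, 1.0)), np.nan)
    if r.ndim == 0:
        return float(r)
    return r


def compute_dic(deviance_trace: np.ndarray, deviance_at_mean: float) -> dict:
    """Deviance information criterion, Spiegelhalter form.

    DIC = Dbar + pD with pD = Dbar - D(theta_bar), where D(theta_bar) is
    the deviance evaluated at the posterior mean of the model parameters.
    """
    dev = np.asarray(deviance_trace, dtype=np.float64)
    if dev.size < 30:
        raise ValueError(
            f"need at least 30 retained deviance samples for DIC, got {dev.size}"
        )
    dbar = float(dev.mean())
    p_d = dbar - float(deviance_at_mean)
    return {"dic": dbar + p_d, "dbar": dbar, "p_d": p_d}


@dataclass
class RegionGenomicParams:
    """Posterior summary of one region's genomic parameters."""

    region_index: int
    chromosome: int
    start_bp: int
    end_bp: int
    n_snp: int
    va_pop1: float
    va_pop2: float
    cov: float
    corr: float
    prop_va1: float
    prop_va2: float
    prop_cov: float
    se_va_pop1: float
    se_va_pop2: float
    se_cov: float
    se_corr: float
    n_corr_excluded: int = 0


@dataclass
class ModelFitReport:
    """Overall fit summary mirroring a variance-component result table."""

    model: str
    va_pop1: float
    va_pop2: float
    cov: float
    corr: float
    ve_pop1: float
    ve_pop2: float
    h2_pop1: float
    h2_pop2: float
    se_va_pop1: float = np.nan
    se_va_pop2: float = np.nan
    se_cov: float = np.nan
    se_corr: float = np.nan
    dic: float = np.nan
    p_d: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def totals_and_h2(
    region_vg: np.ndarray,
    region_cov: np.ndarray,
    residual_var: np.ndarray,
) -> dict:
    """Per-draw totals and heritability-type ratios.

    ``region_vg``: draws x regions x 2; ``region_cov``: draws x regions;
    ``residual_var``: draws x 2.  Totals are plain sums across regions.
    Returns per-draw arrays for total variance (draws x 2), total
    covariance, overall correlation and h2_i = Va_i/(Va_i+Ve_i).
    """
    region_vg = np.asarray(region_vg, dtype=np.float64)
    region_cov = np.asarray(region_cov, dtype=np.float64)
    residual_var = np.asarray(residual_var, dtype=np.float64)
    total_vg = region_vg.sum(axis=1)
    total_cov = region_cov.sum(axis=1)
    corr = region_correlation(total_vg[:, 0], total_vg[:, 1], total_cov)
    h2 = total_vg / (total_vg + residual_var)
    return {"total_vg": total_vg, "total_cov": total_cov,
            "overall_corr": corr, "h2": h2}


def _median_sd(x: np.ndarray, axis=0):
    return np.nanmedian(x, axis=axis), np.nanstd(x, axis=axis)


def summarize_chain(chain, panels, partition=None) -> tuple:
    """Summarize a posterior chain into per-region parameters and a fit report.

    Returns (region_table: DataFrame, report: ModelFitReport).  ``chain`` is
    a :class:`mtgvar.mt_bayes.PosteriorChain`; ``panels`` the two genotype
    panels whose allele frequencies weight the sums; ``partition`` defaults
    to the chain's own partition.
    """
    part = chain.partition if partition is None else partition
    panel1, panel2 = panels
    draws = chain.retained()
    n_draws = draws["var_a"].shape[0]
    n_regions = len(part)

    region_vg = np.empty((n_draws, n_regions, 2))
    region_cov = np.empty((n_draws, n_regions))
    floors = np.empty(2)
    for i, panel in enumerate((panel1, panel2)):
        for j, reg in enumerate(part.regions):
            region_vg[:, j, i] = region_variance_sum(
                panel.allele_freq[reg.slice()], draws["var_a"][:, j, i]
            )
    for j, reg in enumerate(part.regions):
        sl = reg.slice()
        region_cov[:, j] = region_covariance_sum(
            panel1.allele_freq[sl], panel2.allele_freq[sl], draws["cov_a"][:, j]
        )

    tot = totals_and_h2(region_vg, region_cov, draws["sigma2_e"])
    floors = CORR_FLOOR_FACTOR * np.median(tot["total_vg"], axis=0)
    floor = float(max(floors.max(), 0.0))

    prop_vg = region_vg / tot["total_vg"][:, np.newaxis, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_cov = region_cov / tot["total_cov"][:, np.newaxis]

    bed = part.to_dataframe(panel1.map)
    rows = []
    for j in range(n_regions):
        corr_j = region_correlation(
            region_vg[:, j, 0], region_vg[:, j, 1], region_cov[:, j], floor=floor
        )
        n_excl = int(np.sum(~np.isfinite(corr_j)))
        med_v, sd_v = _median_sd(region_vg[:, j, :])
        med_c, sd_c = _median_sd(region_cov[:, j])
        med_r, sd_r = _median_sd(corr_j)
        rows.append(
            RegionGenomicParams(
                region_index=j,
                chromosome=int(bed.loc[j, "chromosome"]),
                start_bp=int(bed.loc[j, "start_bp"]),
                end_bp=int(bed.loc[j, "end_bp"]),
                n_snp=int(bed.loc[j, "n_snp"]),
                va_pop1=float(med_v[0]),
                va_pop2=float(med_v[1]),
                cov=float(med_c),
                corr=float(med_r),
                prop_va1=float(np.median(prop_vg[:, j, 0])),
                prop_va2=float(np.median(prop_vg[:, j, 1])),
                prop_cov=float(np.median(prop_cov[:, j])),
                se_va_pop1=float(sd_v[0]),
                se_va_pop2=float(sd_v[1]),
                se_cov=float(sd_c),
                se_corr=float(sd_r),
                n_corr_excluded=n_excl,
            )
        )
    region_table = pd.DataFrame([asdict(r) for r in rows])

    med_tv, sd_tv = _median_sd(tot["total_vg"])
    med_tc, sd_tc = _median_sd(tot["total_cov"])
    med_r, sd_r = _median_sd(tot["overall_corr"])
    med_ve = np.median(draws["sigma2_e"], axis=0)
    med_h2 = np.median(tot["h2"], axis=0)
    dic = compute_dic(draws["deviance"], chain.deviance_at_posterior_mean())
    report = ModelFitReport(
        model=chain.model,
        va_pop1=float(med_tv[0]),
        va_pop2=float(med_tv[1]),
        cov=float(med_tc),
        corr=float(med_r),
        ve_pop1=float(med_ve[0]),
        ve_pop2=float(med_ve[1]),
        h2_pop1=float(med_h2[0]),
        h2_pop2=float(med_h2[1]),
        se_va_pop1=float(sd_tv[0]),
        se_va_pop2=float(sd_tv[1]),
        se_cov=float(sd_tc),
        se_corr=float(sd_r),
        dic=dic["dic"],
        p_d=dic["p_d"],
    )
    return region_table, report
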