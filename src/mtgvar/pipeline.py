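"""End-to-end workflow: configuration, deterministic run directories and
the synthetic recovery-experiment harness."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .genome_data import partition_regions
from .io import (
    read_genotypes_raw,
    read_marker_map,
    read_phenotypes,
    write_json,
    write_regions_bed,
)
from .mt_bayes import McmcConfig, gibbs_heterogeneous, gibbs_homogeneous
from .mt_gblup import build_grm, gebv_from_components, reml_bivariate
from .summaries import ModelFitReport, summarize_chain
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

#: scenario labels used in logs and manifests for the three partition modes
SCENARIO_NAMES = {
    "all": "all SNP",
    "chromosome": "per chromosome",
    "window": "per window",
}


def parse_partition_mode(mode: str) -> tuple:
    """'all' | 'chromosome' | 'window:N' -> (spec mode, window, merge)."""
    if mode == "all":
        return "all_snp", None, None
    if mode in ("chromosome", "bta"):
        return "per_chromosome", None, None
    if mode.startswith("window"):
        window = int(mode.split(":", 1)[1]) if ":" in mode else 100
        return "fixed_size", window, max(window // 2, 1)
    raise ValueError(f"unknown partition mode {mode!r}")


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source (files or simulation)."""

    out_dir: str
    model: str = "bayes-het"                  # bayes-hom | bayes-het | gblup
    partition_mode: str = "window:100"
    seed: int = 0
    mcmc: McmcConfig = None
    simulation: SimulationConfig | None = None
    genotype_files: tuple | None = None       # ((raw1, map1), (raw2, map2))
    phenotype_file: str | None = None
    trait: str | None = None
    force: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.model not in ("bayes-hom", "bayes-het", "gblup"):
            raise ValueError(f"unknown model {self.model!r}")
        parse_partition_mode(self.partition_mode)
        has_files = self.genotype_files is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("exactly one input source: files or simulation")
        if has_files and self.phenotype_file is None:
            raise ValueError("file input requires a phenotype file")
        if self.mcmc is None:
            self.mcmc = McmcConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "mcmc" in raw and raw["mcmc"] is not None:
            raw["mcmc"] = McmcConfig(**raw["mcmc"])
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "genotype_files" in raw and raw["genotype_files"] is not None:
            raw["genotype_files"] = tuple(tuple(p) for p in raw["genotype_files"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        panels, tables, truth = simulate_dataset(sim)
        manifest_inputs = {
            "source": "simulation",
            "simulation": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(sim).items()
                if k != "region_sigma"
            },
            "region_sigma_sha256": hashlib.sha256(
                np.ascontiguousarray(sim.region_sigma).tobytes()
            ).hexdigest(),
        }
        return panels, tables, truth, manifest_inputs

    (raw1, map1), (raw2, map2) = config.genotype_files
    for p in (raw1, map1, raw2, map2, config.phenotype_file):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file missing: {p}")
    m1 = read_marker_map(map1)
    m2 = read_marker_map(map2)
    panel1 = read_genotypes_raw(raw1, m1, "pop1")
    panel2 = read_genotypes_raw(raw2, m2, "pop2")
    from .genome_data import harmonize_panels

    panel1, panel2 = harmonize_panels(panel1, panel2)
    pheno = read_phenotypes(config.phenotype_file)
    pops = sorted({pop for pop, _ in pheno})
    traits = sorted({t for _, t in pheno})
    trait = config.trait or traits[0]
    if len(pops) != 2:
        raise ValueError(f"need exactly two populations in phenotypes, got {pops}")
    tables = (pheno[(pops[0], trait)], pheno[(pops[1], trait)])
    manifest_inputs = {
        "source": "files",
        "files": {str(p): _sha256(p)
                  for p in (raw1, map1, raw2, map2, config.phenotype_file)},
        "trait": trait,
    }
    return (panel1, panel2), tables, None, manifest_inputs


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured run; returns paths and in-memory results.

    Layout under out_dir: manifest.json, regions.tsv, chain.tsv,
    region_params.tsv, fit_report.json, run.log.  Refuses to overwrite a
    non-empty directory unless ``force`` is set.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    log_lines = []

    def log(msg):
        logger.info(msg)
        log_lines.append(msg)

    mode_key = config.partition_mode.split(":")[0]
    scenario = SCENARIO_NAMES.get("window" if mode_key == "window" else mode_key,
                                  config.partition_mode)
    log(f"mtgvar {__version__} | numpy {np.__version__} | scipy {scipy.__version__} "
        f"| python {platform.python_version()}")
    log(f"seed={config.seed} model={config.model} scenario={scenario!r}")

    panels, tables, truth, manifest_inputs = _load_inputs(config)
    mode, window, merge = parse_partition_mode(config.partition_mode)
    if mode == "fixed_size":
        partition = partition_regions(panels[0].map, mode, window, merge)
    else:
        partition = partition_regions(panels[0].map, mode)
    log(f"{panels[0].n_markers} markers, {len(partition)} regions, "
        f"{panels[0].n_animals}+{panels[1].n_animals} animals")

    write_regions_bed(out / "regions.tsv", partition, panels[0].map)

    results = {"partition": partition, "panels": panels, "tables": tables,
               "truth": truth}
    if config.model == "gblup":
        grm = build_grm(panels)
        comps = reml_bivariate(grm, tables)
        gebv = gebv_from_components(grm, comps, tables)
        va = comps.va
        ve = comps.residual_var
        report = ModelFitReport(
            model="gblup",
            va_pop1=float(va[0]), va_pop2=float(va[1]), cov=comps.cov,
            corr=comps.corr,
            ve_pop1=float(ve[0]), ve_pop2=float(ve[1]),
            h2_pop1=float(va[0] / (va[0] + ve[0])),
            h2_pop2=float(va[1] / (va[1] + ve[1])),
            se_va_pop1=float(comps.se[0]), se_va_pop2=float(comps.se[2]),
            se_cov=float(comps.se[1]), se_corr=comps.corr_se,
        )
        pd.DataFrame(
            {
                "animal_id": grm.animal_id,
                "population": [panels[0].population_id] * panels[0].n_animals
                + [panels[1].population_id] * panels[1].n_animals,
                "gebv_trait1": gebv[:, 0],
                "gebv_trait2": gebv[:, 1],
            }
        ).to_csv(out / "gebv.tsv", sep="\t", index=False)
        results.update(components=comps, gebv=gebv, report=report)
        log(f"AI-REML converged in {comps.n_iter} iterations "
            f"(logL {comps.loglik:.4f})")
    else:
        if config.model == "bayes-hom":
            chain = gibbs_homogeneous(panels, tables, config.mcmc)
        else:
            chain = gibbs_heterogeneous(panels, tables, partition, config.mcmc)
        region_table, report = summarize_chain(chain, panels)
        df = chain.to_dataframe()
        df[chain.retained_mask()].to_csv(out / "chain.tsv", sep="\t", index=False)
        region_table.to_csv(out / "region_params.tsv", sep="\t", index=False)
        results.update(chain=chain, region_table=region_table, report=report)
        log(f"Gibbs run: {config.mcmc.n_cycles} cycles, "
            f"{chain.n_retained} retained samples")

    write_json(out / "fit_report.json", report.to_dict())
    manifest = {
        "tool": "mtgvar",
        "version": __version__,
        "seed": config.seed,
        "model": config.model,
        "scenario": scenario,
        "partition_mode": config.partition_mode,
        "inputs": manifest_inputs,
    }
    write_json(out / "manifest.json", manifest)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    results["report"] = report
    results["out_dir"] = out
    return results


def recovery_experiment(
    sim_config: SimulationConfig,
    models=("bayes-het",),
    n_replicates: int = 10,
    seed: int = 0,
    mcmc: McmcConfig | None = None,
) -> dict:
    """Truth-vs-estimate study over seeded synthetic replicates.

    Returns per-replicate rows and summary bias/RMSE/coverage for total
    variance, covariance and overall correlation, plus per-region
    diagnostics (top-proportion region, region-proportion rank
    correlation) for region-aware models.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    details = []
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        sim = dataclasses.replace(sim_config, seed=rep_seed)
        panels, tables, truth = simulate_dataset(sim)
        for model in models:
            run_mcmc = mcmc or McmcConfig(n_cycles=6000, burn_in=2000, thin=4,
                                          seed=rep_seed)
            run_mcmc = dataclasses.replace(run_mcmc, seed=rep_seed)
            detail = {"replicate": rep, "model": model, "truth": truth}
            if model == "gblup":
                grm = build_grm(panels)
                comps = reml_bivariate(grm, tables)
                est_va = comps.va
                est_cov = comps.cov
                est_corr = comps.corr
                se = {"va1": comps.se[0], "va2": comps.se[2],
                      "cov": comps.se[1], "corr": comps.corr_se}
                detail["components"] = comps
            else:
                if model == "bayes-hom":
                    chain = gibbs_homogeneous(panels, tables, run_mcmc)
                else:
                    chain = gibbs_heterogeneous(
                        panels, tables, truth.partition, run_mcmc
                    )
                region_table, report = summarize_chain(chain, panels)
                est_va = np.array([report.va_pop1, report.va_pop2])
                est_cov = report.cov
                est_corr = report.corr
                se = {"va1": report.se_va_pop1, "va2": report.se_va_pop2,
                      "cov": report.se_cov, "corr": report.se_corr}
                detail["report"] = report
                detail["region_table"] = region_table
                if model == "bayes-het":
                    prop = region_table["prop_va1"].to_numpy()
                    truth_prop = truth.region_vg[:, 0] / truth.region_vg[:, 0].sum()
                    detail["top_region_est"] = int(np.argmax(prop))
                    detail["top_region_truth"] = int(np.argmax(truth_prop))
                    detail["prop_rank_corr"] = float(
                        pd.Series(prop).corr(pd.Series(truth_prop),
                                             method="spearman")
                    )
                    detail["region_corr_est"] = region_table["corr"].to_numpy()
            rows.append(
                {
                    "replicate": rep,
                    "model": model,
                    "va1_true": truth.total_vg[0], "va1_est": est_va[0],
                    "va2_true": truth.total_vg[1], "va2_est": est_va[1],
                    "cov_true": truth.total_cov, "cov_est": est_cov,
                    "corr_true": truth.overall_corr, "corr_est": est_corr,
                    "se_va1": se["va1"], "se_va2": se["va2"],
                    "se_cov": se["cov"], "se_corr": se["corr"],
                }
            )
            details.append(detail)
    table = pd.DataFrame(rows)

    summary = {}
    for model, grp in table.groupby("model"):
        stats = {}
        for name in ("va1", "va2", "cov", "corr"):
            err = grp[f"{name}_est"] - grp[f"{name}_true"]
            cover = np.abs(err) <= 2.0 * grp[f"se_{name}"]
            stats[name] = {
                "bias": float(err.mean()),
                "median_bias": float(err.median()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "coverage_2se": float(cover.mean()),
            }
        summary[model] = stats
    return {"table": table, "summary": summary, "details": details}
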