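"""End-to-end analysis pipeline.

Stage order mirrors the original analysis workflow: simulate (or load)
the cohort, fit the base model, screen and step covariates, run the
goodness-of-fit / VPC / bootstrap evaluation, then the Monte Carlo
target-attainment and redosing simulations.  Every artifact lands in the
output directory with the seed and a config hash in its header; a
machine-readable ``status.json`` records per-stage outcome and timing so
a failed stage leaves the completed artifacts behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import bootstrap
from .cohort import simulate_cohort
from .dataset import PKDataset
from .diagnostics import gof_plots, residuals, simulate_reference, vpc, vpc_plot
from .estimate import SAEMSettings, initial_model, parameter_table, saem_fit
from .io import (RunConfig, config_hash, model_from_config, read_dataset,
                 write_dataset, write_table)
from .pta import EGFR_STRATA, PopulationSpec, pta, redose_time
from .selection import covariate_screen, stepwise_covariates

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


#: stage gates in execution order
ALL_STAGES = ("fit", "diagnostics", "bootstrap", "pta", "redose")


def run_pipeline(cfg: RunConfig, stages=ALL_STAGES) -> dict:
    """Execute the configured stages; returns the status dictionary.

    ``stages`` selects which gates run (the dataset stage always runs);
    estimation is also skipped when ``cfg.fixed_model`` is set, in which
    case diagnostics and simulation use the configured model values.
    """
    stages = set(stages)
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    status = {"seed": cfg.seed, "config_hash": chash, "stages": {}}
    ss = np.random.SeedSequence(cfg.seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
            status["stages"][name] = {"ok": True, "seconds": round(time.time() - t0, 2)}
            logger.info("stage %-16s ok (%.1fs)", name, time.time() - t0)
            return result
        except Exception as exc:  # noqa: BLE001 - recorded and re-raised
            status["stages"][name] = {"ok": False, "error": str(exc)}
            (out / "status.json").write_text(json.dumps(status, indent=2))
            raise

    generating_model = model_from_config(cfg)

    def _data() -> PKDataset:
        if cfg.dataset_path:
            data = read_dataset(cfg.dataset_path)
        else:
            data = simulate_cohort(generating_model, cfg.cohort_spec(), seed=seeds[0])
        write_dataset(data, out / "dataset.csv", seed=cfg.seed, cfg_hash=chash)
        logger.info("dataset: %d subjects, %d observations",
                    data.n_subjects, len(data.observations()))
        return data

    data = stage("dataset", _data)

    if cfg.fixed_model or "fit" not in stages:
        final_model = generating_model
        fit = None
    else:
        st = SAEMSettings(**cfg.estimation) if cfg.estimation else SAEMSettings()

        def _fit():
            base = initial_model(data, template=dataclasses.replace(
                generating_model, covariate_effects={}))
            return saem_fit(data, base, st, seed=seeds[1])

        fit = stage("fit_base", _fit)
        if cfg.run_stepwise:
            def _stepwise():
                cands = covariate_screen(fit, data)
                write_table(pd.DataFrame([dataclasses.asdict(c) for c in cands]),
                            out / "covariate_screen.csv", seed=cfg.seed, cfg_hash=chash)
                return stepwise_covariates(
                    data, fit.model, cands, seed=seeds[2],
                    settings=dataclasses.replace(st, compute_rse=False),
                    ofv_nmc=cfg.ofv_nmc)

            final_model = stage("stepwise", _stepwise)
        else:
            final_model = fit.model

        def _refit():
            return saem_fit(data, final_model, st, seed=seeds[2])

        fit = stage("fit_final", _refit)
        final_model = fit.model
        write_table(parameter_table(fit), out / "parameters.csv",
                    seed=cfg.seed, cfg_hash=chash)

    def _diagnose():
        ref = simulate_reference(final_model, data, nsim=cfg.vpc_nsim, seed=seeds[3])
        res = residuals(final_model, data, ref, fit=fit)
        write_table(res.table, out / "residuals.csv", seed=cfg.seed, cfg_hash=chash)
        bands = vpc(final_model, data, ref=ref, seed=seeds[3])
        write_table(bands.table, out / "vpc.csv", seed=cfg.seed, cfg_hash=chash)
        gof_plots(res, out / "gof.png")
        vpc_plot(bands, data, out / "vpc.png")
        return res

    if "diagnostics" in stages:
        stage("diagnostics", _diagnose)

    if "bootstrap" in stages and fit is not None and cfg.run_bootstrap:
        def _bootstrap():
            bs = bootstrap(data, final_model, n_boot=cfg.n_bootstrap, seed=seeds[4],
                           settings=SAEMSettings(compute_rse=False))
            write_table(bs.summary, out / "bootstrap.csv", seed=cfg.seed, cfg_hash=chash)
            return bs

        stage("bootstrap", _bootstrap)

    def _pta():
        pop = PopulationSpec(n_subjects=cfg.pta_n_subjects,
                             n_replicates=cfg.pta_n_replicates)
        strata = {k: EGFR_STRATA[k] for k in ("full", "below_arc", "arc")}
        table = pta(final_model, pop, mic_grid=cfg.mic_grid,
                    window_min=cfg.pta_window_min, seed=seeds[5], strata=strata)
        wide = table.table.pivot(index="mic", columns="stratum", values="pta_percent")
        write_table(wide.reset_index(), out / "pta.csv", seed=cfg.seed, cfg_hash=chash)
        return table

    if "pta" in stages:
        stage("pta", _pta)

    def _redose():
        pop = PopulationSpec(egfr_range=EGFR_STRATA["arc"],
                             n_subjects=cfg.pta_n_subjects,
                             n_replicates=cfg.pta_n_replicates)
        rows = []
        for mic in sorted(cfg.redose_mics, reverse=True):
            r = redose_time(final_model, pop, mic, coverage=cfg.redose_coverage,
                            seed=seeds[5])
            rows.append({"mic": r.mic, "redose_time_min": r.redose_time_min,
                         "coverage": r.coverage, "achievable": r.achievable})
        write_table(pd.DataFrame(rows), out / "redose.csv",
                    seed=cfg.seed, cfg_hash=chash)
        return rows

    if "redose" in stages:
        stage("redose", _redose)

    (out / "status.json").write_text(json.dumps(status, indent=2))
    return status
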