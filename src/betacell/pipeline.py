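"""End-to-end pipeline: synthesize/load data -> screen -> fit -> PLSR -> perturb.

Every stage writes tidy TSV artifacts plus a JSON manifest (config,
config hash, per-stage seeds, package versions).  A stage failure halts
the pipeline with that stage's error; artifacts written so far are
retained and the manifest marks the run incomplete.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    FitConfig,
    detect_correlated_velocity_pairs,
    efast_sensitivity,
    evaluate_predictions,
    fit_pso,
)
from .config import PipelineConfig
from .datasets import FoldChangeDataset, load_dataset, save_dataset
from .network import build_network, conserved_moieties, parameter_inventory, validate_mass_balance
from .simulate import initial_state, normalize_fluxes_to_glut, steady_state
from .studies import PLSR_TIMEPOINTS, ProtocolSet, insulin_flux_table
from .plsr import FluxInsulinPLS, q2y_loo
from .perturb import SCENARIOS, apply_intervention, scan_vmax
from .synthetic import generate_ground_truth, make_fixture_network, simulate_study

log = logging.getLogger("betacell")


def _model_for(config: PipelineConfig):
    if config.model in ("full", "reduced"):
        return make_fixture_network(config.model)
    import yaml

    return build_network(yaml.safe_load(Path(config.model).read_text()))


def _protocols_for(config: PipelineConfig) -> ProtocolSet:
    return ProtocolSet(low_glucose=config.low_glucose, high_glucose=config.high_glucose,
                       pre_minutes=config.pre_minutes)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "version": __version__,
        "numpy": np.__version__,
        "stages": {},
        "complete": False,
    }

    def checkpoint():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        model = _model_for(config)
        protocols = _protocols_for(config)
        params = model.parameters

        # stage 0: structure report
        log.info("stage structure: %d species / %d reactions", model.n_species, model.n_reactions)
        inv = parameter_inventory(model)
        rels = conserved_moieties(model)
        mb = validate_mass_balance(model)
        (out / "structure.json").write_text(json.dumps({
            "species": model.n_species, "reactions": model.n_reactions,
            "pathways": model.pathway_counts(),
            "parameters": inv.__dict__,
            "conserved_relations": [
                {s: int(c) for s, c in zip(r.species_ids, r.coefficients) if c}
                for r in rels
            ],
            "exchange_reactions": mb.exchange_reactions,
            "internal_sinks": mb.internal_sinks,
            "orphans": mb.orphans,
        }, indent=2))
        manifest["stages"]["structure"] = {"seed": None}
        checkpoint()

        # stage 1: data
        seed = config.stage_seed("synth")
        if config.data:
            dataset = load_dataset(config.data,
                                   valid_metabolites=list(model.metabolite_names()))
            insulin = None
            log.info("stage data: loaded %d observations", len(dataset))
        else:
            truth = generate_ground_truth(model, spread=config.truth_spread, seed=seed)
            study = simulate_study(model, truth, protocols, noise_cv=config.noise_cv,
                                   replicates=config.replicates, seed=seed,
                                   rtol=config.rtol, atol=config.atol)
            dataset = study.dataset()
            insulin = study.insulin
            save_dataset(dataset, out / "observations.tsv")
            study.insulin.to_csv(out / "insulin.tsv", sep="\t", index=False)
            log.info("stage data: synthesized %d observations", len(dataset))
        manifest["stages"]["data"] = {"seed": seed, "n_observations": len(dataset)}
        checkpoint()

        # stage 2: identifiability screen
        pairs = detect_correlated_velocity_pairs(model, params, dataset, protocols)
        pd.DataFrame([{"reaction": r, "vf": p[0], "vr": p[1]} for r, p in pairs]
                     ).to_csv(out / "identifiability.tsv", sep="\t", index=False)
        manifest["stages"]["identifiability"] = {"n_pairs": len(pairs)}
        log.info("stage identifiability: %d correlated pairs", len(pairs))
        checkpoint()

        # stage 3: eFAST selection
        seed = config.stage_seed("efast")
        free = config.free_parameters or _default_free_velocities(model)
        sens = efast_sensitivity(model, params, free, dataset=dataset, protocols=protocols,
                                 range_decades=config.range_decades,
                                 threshold=config.efast_threshold,
                                 n_samples=config.efast_samples, M=config.efast_M,
                                 resamples=config.efast_resamples, seed=seed)
        _write(sens.to_frame(), out / "sensitivity.tsv")
        selection = sens.selection or free  # never fit an empty set
        manifest["stages"]["sensitivity"] = {"seed": seed, "n_selected": len(sens.selection)}
        log.info("stage sensitivity: selected %d of %d", len(sens.selection), len(free))
        checkpoint()

        # stage 4: PSO fit
        seed = config.stage_seed("fit")
        fit_cfg = FitConfig(free_parameters=selection, bound_factor=config.bound_factor,
                            iterations=config.iterations, runs=config.runs,
                            keep_best=config.keep_best, swarm_size=config.swarm_size,
                            seed=seed, rtol=config.fit_rtol, atol=config.fit_atol)
        fit = fit_pso(model, dataset, fit_cfg, protocols=protocols)
        pd.DataFrame({f"fit_{k}": {n: ps[n] for n in selection}
                      for k, ps in enumerate(fit.parameter_sets)}
                     ).to_csv(out / "fitted_parameters.tsv", sep="\t")
        ev = evaluate_predictions(fit, dataset, model=model, protocols=protocols,
                                  replicates=config.replicates)
        _write(ev, out / "fit_evaluation.tsv")
        manifest["stages"]["fit"] = {"seed": seed, "wssr": fit.wssr_values,
                                     "summary": ev.attrs["summary"]}
        log.info("stage fit: best WSSR %.4g", fit.wssr_values[0])
        checkpoint()

        # stage 5: fluxes + PLSR
        init = initial_state(model)
        ss = steady_state(model, fit.parameter_sets[0], init,
                          protocols.boundary(config.high_glucose),
                          horizon=config.steady_horizon, rtol=config.rtol, atol=config.atol)
        flux_pct = normalize_fluxes_to_glut(ss.fluxes, [r.id for r in model.reactions])
        pd.DataFrame({"flux_mM_min": ss.fluxes, "percent_of_glut": flux_pct},
                     index=[r.id for r in model.reactions]
                     ).to_csv(out / "steady_state_fluxes.tsv", sep="\t")
        flux_tables = [insulin_flux_table(model, ps, init, PLSR_TIMEPOINTS, protocols,
                                          rtol=config.rtol, atol=config.atol)
                       for ps in fit.parameter_sets]
        if insulin is None:
            ins_path = out / "insulin.tsv"
            if ins_path.exists():
                insulin = pd.read_csv(ins_path, sep="\t")
            else:
                raise RuntimeError("no insulin response table available for PLSR")
        y = insulin.set_index("time_min").loc[list(PLSR_TIMEPOINTS), "fold_change"]
        ensemble = [FluxInsulinPLS(tab, y, config.n_components,
                                   tuple(config.train_times)).fit()
                    for tab in flux_tables]
        vip = pd.DataFrame({f"fit_{k}": r.vip for k, r in enumerate(ensemble)})
        vip["mean_vip"] = vip.mean(axis=1)
        weights = pd.DataFrame({f"fit_{k}": r.weights for k, r in enumerate(ensemble)})
        weights["mean_weight"] = weights.mean(axis=1)
        _write(vip.sort_values("mean_vip"), out / "plsr_vip.tsv")
        _write(weights, out / "plsr_weights.tsv")
        r2s = [r.r2 for r in ensemble]
        q2s = [r.q2y() for r in ensemble]
        manifest["stages"]["plsr"] = {"r2_mean": float(np.mean(r2s)),
                                      "q2y_mean": float(np.mean(q2s))}
        log.info("stage plsr: mean R2 %.3f, mean Q2Y %.3f", np.mean(r2s), np.mean(q2s))
        checkpoint()

        # stage 6: perturbations
        results = []
        for name in SCENARIOS:
            try:
                res = apply_intervention(model, name, params=fit.parameter_sets[0],
                                         plsr_ensemble=ensemble, protocols=protocols,
                                         glucose=config.high_glucose,
                                         horizon=config.steady_horizon,
                                         insulin_window=config.insulin_window,
                                         rtol=config.rtol, atol=config.atol)
                results.append(res.tidy())
            except KeyError:
                continue
        scan = scan_vmax(model, fit.parameter_sets[0], factor=config.scan_factor,
                         plsr_ensemble=ensemble, protocols=protocols,
                         glucose=config.high_glucose, horizon=config.steady_horizon,
                         insulin_window=config.insulin_window,
                         rtol=config.rtol, atol=config.atol)
        results.extend(r.tidy() for r in scan)
        pd.concat(results, ignore_index=True).to_csv(out / "perturbations.tsv",
                                                     sep="\t", index=False,
                                                     float_format="%.10g")
        manifest["stages"]["perturb"] = {"n_scenarios": len(results)}
        log.info("stage perturb: %d scenarios", len(results))

        manifest["complete"] = True
        checkpoint()
    except Exception:
        checkpoint()
        raise
    return out


def _default_free_velocities(model) -> list[str]:
    """Forward velocities of non-constrained reactions (screen default)."""
    out = []
    for r in model.reactions:
        name = f"Vf_{r.id}"
        if r.rate_law.constrained:
            continue
        if model.parameters is not None and name in model.parameters:
            out.append(name)
    return out
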