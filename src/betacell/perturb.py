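"""Vmax perturbation scans and pharmacological intervention scenarios.

Perturbations multiply a reaction's maximal velocities (both directions
for reversible reactions) by a factor and compare the new high-glucose
steady state against the unperturbed baseline: per-species and pooled
metabolite fold changes, flux fold changes, flux-direction reversals,
and — when a fitted flux->insulin ensemble is supplied — the predicted
insulin effect from time-averaged fluxes.

Registered scenarios:

* ``metformin``      — glucose transport (``glut``) at 20% capacity,
* ``agrimony``       — glucose-6-phosphate dehydrogenase (``g6pd``) 5x,
* ``ak_knockdown``   — adenylate kinase (``ak``) at 20% capacity.

``cmalic`` is accepted as an alias for the cytosolic malic enzyme
(``me1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkModel
from .parameters import ParameterSet
from .plsr import predict_insulin
from .simulate import SteadyStateResult, initial_state, pooled_fold_change, steady_state
from .studies import ProtocolSet, insulin_flux_table

#: scenario name -> (reaction id, Vmax factor)
SCENARIOS: dict[str, tuple[str, float]] = {
    "metformin": ("glut", 0.2),
    "agrimony": ("g6pd", 5.0),
    "ak_knockdown": ("ak", 0.2),
}

REACTION_ALIASES = {"cmalic": "me1", "oxtransfer": "oxtransfer"}

NO_CHANGE_LOG2 = 0.05  # |log2 FC| below this is displayed as "no change"


def _boundary_for(model: NetworkModel, protocols: ProtocolSet | None, glucose: float) -> dict:
    """Protocol boundary restricted to species the model actually clamps."""
    wanted = (protocols or ProtocolSet()).boundary(glucose)
    clamped = {s.id for s in model.boundary_species}
    return {k: v for k, v in wanted.items() if k in clamped}


@dataclass(frozen=True)
class Perturbation:
    reaction: str
    factor: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("perturbation factor must be > 0")


@dataclass
class PerturbationResult:
    perturbation: Perturbation
    species_fold_change: dict[str, float]
    pooled_fold_change: dict[str, float]
    flux_fold_change: dict[str, float]
    flux_reversals: list[str]
    insulin_fold_change: float | None
    converged: bool
    no_change: list[str] = field(default_factory=list)

    def tidy(self) -> pd.DataFrame:
        """Heatmap-ready (perturbation, target, fold_change) rows."""
        rows = [
            {"perturbation": self.perturbation.label or self.perturbation.reaction,
             "target": name, "kind": "metabolite", "fold_change": fc}
            for name, fc in self.pooled_fold_change.items()
        ] + [
            {"perturbation": self.perturbation.label or self.perturbation.reaction,
             "target": rid, "kind": "flux", "fold_change": fc}
            for rid, fc in self.flux_fold_change.items()
        ]
        if self.insulin_fold_change is not None:
            rows.append({"perturbation": self.perturbation.label or self.perturbation.reaction,
                         "target": "insulin", "kind": "insulin",
                         "fold_change": self.insulin_fold_change})
        return pd.DataFrame(rows)


def _velocity_names(model: NetworkModel, reaction: str) -> list[str]:
    """Parameter names bound to the reaction's velocity roles.

    A constrained reaction derives Vr from Vf/Keq, so scaling Vf alone
    scales the whole (net) rate law.
    """
    rxn = model.reactions[model.reaction_index[reaction]]
    pm = rxn.rate_law.parameter_names
    roles = ["Vf", "kf"] if rxn.rate_law.constrained else ["Vf", "Vr", "kf", "kr"]
    names = [pm[r] for r in roles if r in pm]
    if not names:
        raise KeyError(f"reaction {reaction!r} has no velocity parameters")
    return names


def perturbed_parameters(model: NetworkModel, perturbation: Perturbation) -> ParameterSet:
    rid = REACTION_ALIASES.get(perturbation.reaction, perturbation.reaction)
    if rid not in model.reaction_index:
        raise KeyError(f"unknown reaction {rid!r}")
    params = model.parameters
    for name in _velocity_names(model, rid):
        params = params.scaled(name, perturbation.factor)
    return params


def _compare(model: NetworkModel, baseline: SteadyStateResult,
             perturbed: SteadyStateResult, perturbation: Perturbation,
             insulin_fc: float | None) -> PerturbationResult:
    sfc = {}
    for sid, b, p in zip(baseline.species_ids, baseline.state, perturbed.state):
        sfc[sid] = float(p / b) if b > 1e-9 else float("nan")
    pooled = pooled_fold_change(model, perturbed.state, baseline.state,
                                comparison="high_vs_low").values
    ffc, reversals = {}, []
    for rid, b, p in zip(baseline.reaction_ids, baseline.fluxes, perturbed.fluxes):
        ffc[rid] = float(p / b) if abs(b) > 1e-12 else float("nan")
        if b * p < 0 and max(abs(b), abs(p)) > 1e-9:
            reversals.append(rid)
    no_change = [name for name, fc in pooled.items()
                 if fc > 0 and abs(np.log2(fc)) < NO_CHANGE_LOG2]
    return PerturbationResult(
        perturbation=perturbation, species_fold_change=sfc,
        pooled_fold_change=pooled, flux_fold_change=ffc,
        flux_reversals=reversals, insulin_fold_change=insulin_fc,
        converged=perturbed.converged, no_change=no_change,
    )


def _insulin_effect_for(model: NetworkModel, params: ParameterSet,
                        baseline_params: ParameterSet, init: np.ndarray,
                        ensemble, protocols: ProtocolSet,
                        window: float, rtol: float, atol: float) -> float | None:
    if ensemble is None:
        return None
    tab_p = insulin_flux_table(model, params, init, (window,), protocols,
                               rtol=rtol, atol=atol)
    tab_b = insulin_flux_table(model, baseline_params, init, (window,), protocols,
                               rtol=rtol, atol=atol)
    return insulin_effect(tab_p.iloc[0].to_numpy(), ensemble, tab_b.iloc[0].to_numpy())


def insulin_effect(perturbed_fluxes: np.ndarray, ensemble, baseline_fluxes: np.ndarray) -> float:
    """Ratio of ensemble-predicted insulin: perturbed over baseline fluxes."""
    # accept PLSResults objects or raw PLSRFit objects
    models = ensemble if isinstance(ensemble, (list, tuple)) else [ensemble]
    fits = [getattr(m, "fit", m) for m in models]
    num = predict_insulin(fits, perturbed_fluxes)
    den = predict_insulin(fits, baseline_fluxes)
    if den == 0:
        raise ZeroDivisionError("baseline insulin prediction is zero")
    return num / den


def apply_intervention(model: NetworkModel, scenario: str | Perturbation,
                       params: ParameterSet | None = None,
                       baseline: SteadyStateResult | None = None,
                       plsr_ensemble=None,
                       protocols: ProtocolSet | None = None,
                       glucose: float = 16.7, horizon: float = 4320.0,
                       insulin_window: float = 60.0,
                       rtol: float = 1e-8, atol: float = 1e-10) -> PerturbationResult:
    """Simulate a named (or custom) intervention at high glucose.

    Steady state vs steady state under the 16.7 mM condition; an unknown
    scenario name raises listing the registry.
    """
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise KeyError(
                f"unknown scenario {scenario!r}; registered: {sorted(SCENARIOS)}"
            )
        rid, factor = SCENARIOS[scenario]
        perturbation = Perturbation(reaction=rid, factor=factor, label=scenario)
    else:
        perturbation = scenario
    params = params or model.parameters
    base_model_params = params
    init = initial_state(model)
    boundary = _boundary_for(model, protocols, glucose)
    if baseline is None:
        baseline = steady_state(model, params, init, boundary, horizon=horizon,
                                rtol=rtol, atol=atol)
    rid = REACTION_ALIASES.get(perturbation.reaction, perturbation.reaction)
    if rid not in model.reaction_index:
        raise KeyError(f"unknown reaction {rid!r}")
    pparams = params
    for name in _velocity_names(model, rid):
        pparams = pparams.scaled(name, perturbation.factor)
    perturbed = steady_state(model, pparams, np.asarray(baseline.state), boundary,
                             horizon=horizon, rtol=rtol, atol=atol)
    if not perturbed.converged:
        warnings.warn(f"perturbation {perturbation} did not certify steady state")
    insulin_fc = _insulin_effect_for(model, pparams, base_model_params, init,
                                     plsr_ensemble, protocols or ProtocolSet(),
                                     insulin_window, rtol, atol)
    return _compare(model, baseline, perturbed, perturbation, insulin_fc)


def scan_vmax(model: NetworkModel, params: ParameterSet | None = None,
              factor: float = 2.0, reactions: list[str] | None = None,
              plsr_ensemble=None, protocols: ProtocolSet | None = None,
              glucose: float = 16.7, horizon: float = 4320.0,
              insulin_window: float = 60.0,
              rtol: float = 1e-8, atol: float = 1e-10) -> list[PerturbationResult]:
    """Double and halve every reaction's Vmax, comparing steady states.

    Per-scenario simulation failures are recorded (NaN fold changes) and
    the scan continues.
    """
    params = params or model.parameters
    init = initial_state(model)
    boundary = _boundary_for(model, protocols, glucose)
    baseline = steady_state(model, params, init, boundary, horizon=horizon,
                            rtol=rtol, atol=atol)
    reactions = reactions or [r.id for r in model.reactions]
    out = []
    for rid in reactions:
        for f in (factor, 1.0 / factor):
            pert = Perturbation(reaction=rid, factor=f, label=f"{rid} x{f:g}")
            try:
                res = apply_intervention(model, pert, params=params, baseline=baseline,
                                         plsr_ensemble=plsr_ensemble, protocols=protocols,
                                         glucose=glucose, horizon=horizon,
                                         insulin_window=insulin_window,
                                         rtol=rtol, atol=atol)
            except Exception as exc:
                warnings.warn(f"scan scenario {pert.label} failed: {exc}")
                res = PerturbationResult(
                    perturbation=pert, species_fold_change={}, pooled_fold_change={},
                    flux_fold_change={}, flux_reversals=[], insulin_fold_change=None,
                    converged=False,
                )
            out.append(res)
    return out
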