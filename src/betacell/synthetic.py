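"""Ground-truth-known synthetic studies.

Every pipeline stage is testable without downloads: a reduced fixture
network (glycolysis trunk, a two-compartment malate shuttle, the NAD
redox pair) stands in for the full network, a "true" parameter set is
sampled around the nominal values, fold-change observations are
simulated with multiplicative log-normal noise, and a synthetic insulin
response is generated as a recorded linear combination of three
designated reaction fluxes.  Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datasets import (
    FoldChangeDataset,
    STUDY_COMPARISON,
    STUDY_METABOLITES,
    STUDY_TIMEPOINTS,
)
from .network import NetworkModel, build_network
from .parameters import ParameterSet
from .simulate import initial_state
from .studies import PLSR_TIMEPOINTS, ProtocolSet, insulin_flux_table, predicted_fold_changes

# ---------------------------------------------------------------------------
# fixture networks

#: the reduced fixture: 12 dynamic species, 14 reactions, one conserved
#: cofactor pair (NAD-NADH), two compartments plus medium, a reversible
#: malate shuttle and lumped glycolysis/TCA segments.
REDUCED_DEFINITION: dict = {
    "name": "reduced_fixture",
    "compartments": [
        {"id": "e", "name": "extracellular", "relative_volume": 10.0},
        {"id": "c", "name": "cytosol", "relative_volume": 3.0},
        {"id": "m", "name": "mitochondria", "relative_volume": 1.0},
    ],
    "species": [
        {"id": "GLC_e", "name": "GLC_ext", "compartment": "e", "init": 2.8, "boundary": True, "pathway": "exchange"},
        {"id": "LAC_e", "name": "LAC_ext", "compartment": "e", "init": 0.5, "boundary": True, "pathway": "exchange"},
        {"id": "GLC_c", "name": "GLC", "compartment": "c", "init": 1.5, "pathway": "glycolysis"},
        {"id": "G6P_c", "name": "G6P", "compartment": "c", "init": 0.3, "pathway": "glycolysis"},
        {"id": "TRI_c", "name": "TRI", "compartment": "c", "init": 0.2, "pathway": "glycolysis"},
        {"id": "PYR_c", "name": "PYR", "compartment": "c", "init": 0.1, "pathway": "glycolysis"},
        {"id": "LAC_c", "name": "LAC", "compartment": "c", "init": 0.5, "pathway": "glycolysis"},
        {"id": "NAD_c", "name": "NAD", "compartment": "c", "init": 0.45, "pathway": "etc"},
        {"id": "NADH_c", "name": "NADH", "compartment": "c", "init": 0.05, "pathway": "etc"},
        {"id": "PYR_m", "name": "PYR", "compartment": "m", "init": 0.1, "pathway": "tca"},
        {"id": "OAA_m", "name": "OAA", "compartment": "m", "init": 0.05, "pathway": "tca"},
        {"id": "CIT_m", "name": "CIT", "compartment": "m", "init": 0.3, "pathway": "tca"},
        {"id": "MAL_m", "name": "MAL", "compartment": "m", "init": 0.3, "pathway": "tca"},
        {"id": "MAL_c", "name": "MAL", "compartment": "c", "init": 0.3, "pathway": "tca"},
    ],
    "reactions": [
        {"id": "glut", "pathway": "glycolysis", "compartment": "c", "reversible": True,
         "template": "transport_rev",
         "substrates": {"GLC_e": 1}, "products": {"GLC_c": 1},
         "params": {"Vf": "Vf_glut", "Vr": "Vr_glut", "Km_out": "Km_glut_out", "Km_in": "Km_glut_in"}},
        {"id": "hk", "pathway": "glycolysis", "compartment": "c",
         "template": "irreversible_mm",
         "substrates": {"GLC_c": 1}, "products": {"G6P_c": 1},
         "params": {"Vf": "Vf_hk", "Km.GLC_c": "Km_hk_GLC"}},
        {"id": "pfka", "pathway": "glycolysis", "compartment": "c",
         "template": "irreversible_mm",
         "substrates": {"G6P_c": 1}, "products": {"TRI_c": 2},
         "params": {"Vf": "Vf_pfka", "Km.G6P_c": "Km_pfka_G6P"}},
        {"id": "gld", "pathway": "glycolysis", "compartment": "c", "reversible": True,
         "template": "reversible_mm",
         "substrates": {"TRI_c": 1, "NAD_c": 1}, "products": {"PYR_c": 1, "NADH_c": 1},
         "params": {"Vf": "Vf_gld", "Vr": "Vr_gld", "Km.TRI_c": "Km_gld_TRI",
                    "Km.NAD_c": "Km_gld_NAD", "Km.PYR_c": "Km_gld_PYR", "Km.NADH_c": "Km_gld_NADH"}},
        {"id": "ldh", "pathway": "glycolysis", "compartment": "c", "reversible": True,
         "template": "reversible_mm",
         "substrates": {"PYR_c": 1, "NADH_c": 1}, "products": {"LAC_c": 1, "NAD_c": 1},
         "params": {"Vf": "Vf_ldh", "Vr": "Vr_ldh", "Km.PYR_c": "Km_ldh_PYR",
                    "Km.NADH_c": "Km_ldh_NADH", "Km.LAC_c": "Km_ldh_LAC", "Km.NAD_c": "Km_ldh_NAD"}},
        {"id": "mct", "pathway": "glycolysis", "compartment": "c",
         "template": "facilitated_transport",
         "substrates": {"LAC_c": 1}, "products": {"LAC_e": 1},
         "params": {"Vf": "Vf_mct", "Km": "Km_mct"}},
        {"id": "pyrt", "pathway": "tca", "compartment": "m", "reversible": True,
         "template": "transport_rev",
         "substrates": {"PYR_c": 1}, "products": {"PYR_m": 1},
         "params": {"Vf": "Vf_pyrt", "Vr": "Vr_pyrt", "Km_out": "Km_pyrt_out", "Km_in": "Km_pyrt_in"}},
        {"id": "pc", "pathway": "tca", "compartment": "m",
         "template": "irreversible_mm",
         "substrates": {"PYR_m": 1}, "products": {"OAA_m": 1},
         "params": {"Vf": "Vf_pc", "Km.PYR_m": "Km_pc_PYR"}},
        {"id": "pdhcs", "pathway": "tca", "compartment": "m",
         "template": "irreversible_mm",
         "substrates": {"PYR_m": 1, "OAA_m": 1, "NAD_c": 1}, "products": {"CIT_m": 1, "NADH_c": 1},
         "params": {"Vf": "Vf_pdhcs", "Km.PYR_m": "Km_pdhcs_PYR", "Km.OAA_m": "Km_pdhcs_OAA",
                    "Km.NAD_c": "Km_pdhcs_NAD"}},
        {"id": "citox", "pathway": "tca", "compartment": "m",
         "template": "irreversible_mm",
         "substrates": {"CIT_m": 1, "NAD_c": 1}, "products": {"MAL_m": 1, "NADH_c": 1},
         "params": {"Vf": "Vf_citox", "Km.CIT_m": "Km_citox_CIT", "Km.NAD_c": "Km_citox_NAD"}},
        {"id": "mdhm", "pathway": "tca", "compartment": "m", "reversible": True,
         "template": "reversible_mm",
         "substrates": {"MAL_m": 1, "NAD_c": 1}, "products": {"OAA_m": 1, "NADH_c": 1},
         "params": {"Vf": "Vf_mdhm", "Vr": "Vr_mdhm", "Km.MAL_m": "Km_mdhm_MAL",
                    "Km.NAD_c": "Km_mdhm_NAD", "Km.OAA_m": "Km_mdhm_OAA", "Km.NADH_c": "Km_mdhm_NADH"}},
        {"id": "malt", "pathway": "tca", "compartment": "c", "reversible": True,
         "template": "transport_rev",
         "substrates": {"MAL_m": 1}, "products": {"MAL_c": 1},
         "params": {"Vf": "Vf_malt", "Vr": "Vr_malt", "Km_out": "Km_malt_out", "Km_in": "Km_malt_in"}},
        {"id": "mec", "pathway": "tca", "compartment": "c",
         "template": "irreversible_mm",
         "substrates": {"MAL_c": 1, "NAD_c": 1}, "products": {"PYR_c": 1, "NADH_c": 1},
         "params": {"Vf": "Vf_mec", "Km.MAL_c": "Km_mec_MAL", "Km.NAD_c": "Km_mec_NAD"}},
        {"id": "nadox", "pathway": "etc", "compartment": "c",
         "template": "etc_complex",
         "substrates": {"NADH_c": 1}, "products": {"NAD_c": 1},
         "params": {"Vf": "Vf_nadox", "Km.NADH_c": "Km_nadox_NADH"}},
        {"id": "glys", "pathway": "other", "compartment": "c",
         "template": "irreversible_mm",
         "substrates": {"G6P_c": 1}, "products": {},
         "params": {"Vf": "Vf_glys", "Km.G6P_c": "Km_glys_G6P"}},
    ],
    "parameters": {
        "Vf_glut": {"value": 2.0, "class": "velocity"}, "Vr_glut": {"value": 2.0, "class": "velocity"},
        "Km_glut_out": {"value": 12.0, "class": "michaelis"}, "Km_glut_in": {"value": 12.0, "class": "michaelis"},
        "Vf_hk": {"value": 1.5, "class": "velocity"}, "Km_hk_GLC": {"value": 7.0, "class": "michaelis"},
        "Vf_pfka": {"value": 0.8, "class": "velocity"}, "Km_pfka_G6P": {"value": 0.4, "class": "michaelis"},
        "Vf_gld": {"value": 8.0, "class": "velocity"}, "Vr_gld": {"value": 1.0, "class": "velocity"},
        "Km_gld_TRI": {"value": 1.0, "class": "michaelis"}, "Km_gld_NAD": {"value": 0.3, "class": "michaelis"},
        "Km_gld_PYR": {"value": 0.5, "class": "michaelis"}, "Km_gld_NADH": {"value": 0.05, "class": "michaelis"},
        "Vf_ldh": {"value": 3.0, "class": "velocity"}, "Vr_ldh": {"value": 0.5, "class": "velocity"},
        "Km_ldh_PYR": {"value": 0.3, "class": "michaelis"}, "Km_ldh_NADH": {"value": 0.05, "class": "michaelis"},
        "Km_ldh_LAC": {"value": 2.0, "class": "michaelis"}, "Km_ldh_NAD": {"value": 0.3, "class": "michaelis"},
        "Vf_mct": {"value": 2.5, "class": "velocity"}, "Km_mct": {"value": 3.0, "class": "michaelis"},
        "Vf_pyrt": {"value": 3.0, "class": "velocity"}, "Vr_pyrt": {"value": 3.0, "class": "velocity"},
        "Km_pyrt_out": {"value": 0.3, "class": "michaelis"}, "Km_pyrt_in": {"value": 0.5, "class": "michaelis"},
        "Vf_pc": {"value": 0.3, "class": "velocity"}, "Km_pc_PYR": {"value": 0.4, "class": "michaelis"},
        "Vf_pdhcs": {"value": 2.0, "class": "velocity"}, "Km_pdhcs_PYR": {"value": 0.2, "class": "michaelis"},
        "Km_pdhcs_OAA": {"value": 0.1, "class": "michaelis"}, "Km_pdhcs_NAD": {"value": 0.3, "class": "michaelis"},
        "Vf_citox": {"value": 1.5, "class": "velocity"}, "Km_citox_CIT": {"value": 0.5, "class": "michaelis"},
        "Km_citox_NAD": {"value": 0.3, "class": "michaelis"},
        "Vf_mdhm": {"value": 6.0, "class": "velocity"}, "Vr_mdhm": {"value": 2.0, "class": "velocity"},
        "Km_mdhm_MAL": {"value": 0.5, "class": "michaelis"}, "Km_mdhm_NAD": {"value": 0.3, "class": "michaelis"},
        "Km_mdhm_OAA": {"value": 0.04, "class": "michaelis"}, "Km_mdhm_NADH": {"value": 0.05, "class": "michaelis"},
        "Vf_malt": {"value": 0.8, "class": "velocity"}, "Vr_malt": {"value": 0.5, "class": "velocity"},
        "Km_malt_out": {"value": 0.5, "class": "michaelis"}, "Km_malt_in": {"value": 0.5, "class": "michaelis"},
        "Vf_mec": {"value": 0.15, "class": "velocity"}, "Km_mec_MAL": {"value": 0.5, "class": "michaelis"},
        "Km_mec_NAD": {"value": 0.3, "class": "michaelis"},
        "Vf_nadox": {"value": 1.2, "class": "velocity"}, "Km_nadox_NADH": {"value": 0.05, "class": "michaelis"},
        "Vf_glys": {"value": 0.05, "class": "velocity"}, "Km_glys_G6P": {"value": 0.5, "class": "michaelis"},
    },
    "equilibrium_pairs": [],
}

#: reactions whose fluxes drive the synthetic insulin response.  The
#: reduced-fixture drivers are the pyruvate/malate-cycling fluxes
#: (mitochondrial malate dehydrogenase, malate transport, cytosolic
#: malic enzyme) — the one axis of the fixture whose time-averaged flux
#: profiles are mutually distinguishable under the nested averaging
#: windows, which makes VIP-based driver recovery well-posed.  The
#: negative intercept turns the flux combination into a fold-change-like
#: response with realistic dynamic range.
REDUCED_INSULIN_DRIVERS = {"mdhm": 20.0, "malt": 4.0, "mec": -4.0}
REDUCED_INSULIN_INTERCEPT = -4.0
FULL_INSULIN_DRIVERS = {"pyk": 0.9, "pdh": 1.4, "ak": -0.8}
FULL_INSULIN_INTERCEPT = -1.0


def make_fixture_network(size: str = "reduced") -> NetworkModel:
    """Build the reduced fixture or the complete beta-cell network.

    ``"reduced"`` is the ~12-species test-bed used throughout the suite;
    ``"full"`` loads the shipped 56-species / 65-reaction definition.
    """
    if size == "reduced":
        return build_network(REDUCED_DEFINITION)
    if size == "full":
        return load_full_network()
    raise ValueError(f"unknown fixture size {size!r} (use 'reduced' or 'full')")


def load_full_network() -> NetworkModel:
    ref = importlib.resources.files("betacell").joinpath("models/beta_cell.yml")
    with ref.open("r") as fh:
        definition = yaml.safe_load(fh)
    return build_network(definition)


# ---------------------------------------------------------------------------
# generators


def generate_ground_truth(model: NetworkModel, spread: float = 0.3,
                          seed: int | np.random.Generator = 0,
                          bound_factor: float = 100.0,
                          names: list[str] | None = None) -> ParameterSet:
    """Sample a "true" parameter set around the nominal values.

    Maximal velocities are drawn log-normally with log-sd ``spread``;
    draws outside the multiplicative fitting bounds are redrawn (up to
    100 tries) then clipped with a warning.  ``spread=0`` returns the
    nominal set.  ``names`` restricts the draw to a subset of the
    velocities (used by the parameter-recovery experiments, where only
    the fitted parameters may differ from nominal).
    """
    if model.parameters is None:
        raise ValueError("model carries no nominal parameters")
    rng = np.random.default_rng(seed)
    params = model.parameters.copy()
    new = {}
    for name in (names if names is not None else params.names_of_class("velocity")):
        nominal = params[name]
        if nominal == 0 or spread == 0:
            new[name] = nominal
            continue
        lo, hi = nominal / bound_factor, nominal * bound_factor
        value = None
        for _ in range(100):
            cand = nominal * np.exp(rng.normal(0.0, spread))
            if lo <= cand <= hi:
                value = cand
                break
        if value is None:
            value = float(np.clip(nominal * np.exp(rng.normal(0.0, spread)), lo, hi))
            warnings.warn(f"{name}: ground-truth draw clipped to bounds")
        new[name] = value
    out = params.updated(new, provenance="sampled")
    return out


@dataclass
class SyntheticStudy:
    """A simulated metabolomics + insulin study with known ground truth."""

    ground_truth: ParameterSet
    noiseless: pd.DataFrame
    observations: pd.DataFrame  # the FoldChangeDataset schema
    insulin: pd.DataFrame  # time_min, fold_change, sd
    insulin_noiseless: pd.DataFrame
    driver_coefficients: dict[str, float]
    driver_intercept: float
    seed: int | None
    config: dict = field(default_factory=dict)
    valid: bool = True

    def dataset(self) -> FoldChangeDataset:
        return FoldChangeDataset(self.observations)


def _study_design_for(model: NetworkModel) -> dict[str, list[str]]:
    """Per-study metabolite lists, restricted to names the model carries."""
    names = set(model.metabolite_names())
    if names.issuperset(STUDY_METABOLITES["spegel2013"]):
        return {k: list(v) for k, v in STUDY_METABOLITES.items()}
    # reduced fixture: measure what exists
    base = sorted(n for n in names if n not in ("NAD", "NADH"))
    return {"spegel2013": base, "malmgren": base, "spegel2015": base}


def simulate_study(model: NetworkModel, truth: ParameterSet,
                   protocols: ProtocolSet | None = None,
                   noise_cv: float = 0.15, replicates: int = 3,
                   seed: int | None = 0,
                   drivers: dict[str, float] | None = None,
                   driver_intercept: float | None = None,
                   rtol: float = 1e-8, atol: float = 1e-10) -> SyntheticStudy:
    """Simulate the emulated studies and add multiplicative noise.

    Observation value = mean over ``replicates`` log-normal draws around
    the noiseless fold change (sd column = sample sd); with
    ``noise_cv=0`` the observations equal the noiseless simulation and
    sd is 0.  The synthetic insulin fold change at each time point is
    ``intercept + sum_k w_k * mean-flux_k([0, t])`` with the recorded
    driver weights, plus the same noise model.
    """
    ps = protocols or ProtocolSet()
    rng = np.random.default_rng(seed)
    init = initial_state(model)
    sigma = np.log1p(noise_cv)

    try:
        fcs = predicted_fold_changes(model, truth, init, ps, rtol=rtol, atol=atol)
        flux_tab = insulin_flux_table(model, truth, init, PLSR_TIMEPOINTS, ps, rtol=rtol, atol=atol)
    except Exception as exc:  # non-converged simulation invalidates the study
        raise RuntimeError(f"synthetic study simulation failed: {exc}") from exc

    design = _study_design_for(model)
    rows_clean, rows_noisy = [], []
    for source, mets in design.items():
        comparison = STUDY_COMPARISON[source]
        for role, times in STUDY_TIMEPOINTS[source].items():
            for t in times:
                values = fcs[(source, t, comparison)]
                for met in mets:
                    clean = values[met]
                    if noise_cv > 0:
                        draws = clean * np.exp(rng.normal(0.0, sigma, size=replicates))
                        value, sd = float(np.mean(draws)), float(np.std(draws, ddof=1))
                    else:
                        value, sd = float(clean), 0.0
                    base = dict(metabolite=met, time_min=t, comparison=comparison,
                                source=source, role=role)
                    rows_clean.append({**base, "fold_change": float(clean), "sd": 0.0})
                    rows_noisy.append({**base, "fold_change": value, "sd": sd})

    if drivers is not None:
        drv = dict(drivers)
        if driver_intercept is None:
            driver_intercept = 0.25
    elif set(FULL_INSULIN_DRIVERS) <= set(model.reaction_index):
        drv = dict(FULL_INSULIN_DRIVERS)
        if driver_intercept is None:
            driver_intercept = FULL_INSULIN_INTERCEPT
    else:
        drv = dict(REDUCED_INSULIN_DRIVERS)
        if driver_intercept is None:
            driver_intercept = REDUCED_INSULIN_INTERCEPT
    missing = [r for r in drv if r not in model.reaction_index]
    if missing:
        raise ValueError(f"insulin driver reactions not in model: {missing}")
    ins_clean, ins_noisy = [], []
    for t in PLSR_TIMEPOINTS:
        resp = driver_intercept + sum(w * flux_tab.loc[t, r] for r, w in drv.items())
        resp = float(max(resp, 1e-3))
        if noise_cv > 0:
            draws = resp * np.exp(rng.normal(0.0, sigma, size=replicates))
            value, sd = float(np.mean(draws)), float(np.std(draws, ddof=1))
        else:
            value, sd = resp, 0.0
        ins_clean.append({"time_min": t, "fold_change": resp, "sd": 0.0})
        ins_noisy.append({"time_min": t, "fold_change": value, "sd": sd})

    cols = ["metabolite", "time_min", "comparison", "fold_change", "sd", "source", "role"]
    return SyntheticStudy(
        ground_truth=truth,
        noiseless=pd.DataFrame(rows_clean)[cols],
        observations=pd.DataFrame(rows_noisy)[cols],
        insulin=pd.DataFrame(ins_noisy),
        insulin_noiseless=pd.DataFrame(ins_clean),
        driver_coefficients=drv,
        driver_intercept=driver_intercept,
        seed=seed if isinstance(seed, int) else None,
        config={"noise_cv": noise_cv, "replicates": replicates,
                "protocols": ps.__dict__.copy()},
    )
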