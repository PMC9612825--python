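"""Enzyme rate-law templates.

Every reaction in a network carries a :class:`~betacell.network.RateLawSpec`
naming one of the templates below plus a role->parameter-name map.  The
templates are deliberately small in number; the biochemistry-specific
content (which species, which regulators, which constants) lives in the
model-definition document.

Conventions
-----------
* Concentrations in mM, velocities in mM/min.
* ``irreversible_mm`` — product of saturating substrate terms, optional
  Hill exponents, optional competitive product binding, optional
  saturating activator / inhibitor modifiers::

      v = Vf * prod_s [(S/Km_s)^n_s / (1 + (S/Km_s)^n_s)]^c_s
             / (1 + sum_p P/Kp_p) * prod_mod

* ``reversible_mm`` — lumped reversible Michaelis-Menten (uni-uni up to
  bi-bi) with the reverse numerator scaled over the substrate Michaelis
  constants so that the net rate vanishes exactly when
  ``prod(P^cp) / prod(S^cs) = Vf / Vr``::

      v = (Vf * prod_s S^cs - Vr * prod_p P^cp) / prod_s Km_s^cs
          / [prod_s (1 + S/Km_s)^cs + prod_p (1 + P/Km_p)^cp - 1 + cross]

  A reaction flagged ``constrained`` derives ``Vr = Vf / Keq``; its net
  rate is then zero exactly at the equilibrium ratio ``prod P / prod S =
  Keq`` (Haldane-style constraint used by the identifiability screen).
* ``facilitated_transport`` — symmetric carrier,
  ``v = Vf (S_out - S_in) / (Km + S_out + S_in)``.
* ``transport_rev`` — asymmetric carrier with independent forward and
  reverse velocities, ``v = Vf So/(Km_out+So) - Vr Si/(Km_in+Si)``.
* ``mass_action`` — ``v = kf prod S^cs - kr prod P^cp``.
* ``etc_complex`` — alias of ``irreversible_mm``; used to tag the
  phenomenological electron-transport-chain steps.

Negative concentrations (solver round-off) are clamped to zero inside
the compiled rates; the clamp tolerance is enforced by the simulator.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

TEMPLATES = (
    "irreversible_mm",
    "irreversible_mm_1s",
    "irreversible_mm_2s",
    "reversible_mm",
    "reversible_uni_uni_haldane",
    "ordered_bi_bi",
    "facilitated_transport",
    "transport_rev",
    "mass_action",
    "etc_complex",
)

# aliases: the spec-level template vocabulary maps onto the two generic
# Michaelis-Menten engines
_ALIASES = {
    "irreversible_mm_1s": "irreversible_mm",
    "irreversible_mm_2s": "irreversible_mm",
    "etc_complex": "irreversible_mm",
    "reversible_uni_uni_haldane": "reversible_mm",
    "ordered_bi_bi": "reversible_mm",
}


class RateLawError(ValueError):
    """Raised when a rate law references missing parameters or species."""


def canonical_template(name: str) -> str:
    if name not in TEMPLATES:
        raise RateLawError(f"unknown rate-law template {name!r}")
    return _ALIASES.get(name, name)


def _p(params: Mapping[str, float], pname_map: Mapping[str, str], role: str, rxn_id: str) -> float:
    try:
        name = pname_map[role]
    except KeyError as exc:
        raise RateLawError(f"reaction {rxn_id!r}: rate law needs role {role!r}") from exc
    try:
        return float(params[name])
    except KeyError as exc:
        raise RateLawError(f"reaction {rxn_id!r}: parameter {name!r} not in parameter set") from exc


def compile_rate(reaction, species_index: Mapping[str, int], params: Mapping[str, float]) -> Callable[[np.ndarray], float]:
    """Compile a reaction's rate law into ``f(concentrations) -> mM/min``.

    ``species_index`` maps species id -> position in the concentration
    vector (boundary species included; the simulator appends them).
    Parameter values are frozen into the closure, so re-compile after
    changing parameters.
    """
    rl = reaction.rate_law
    tmpl = canonical_template(rl.template)
    pm = rl.parameter_names
    rid = reaction.id

    subs = [(sid, species_index[sid], c) for sid, c in reaction.substrates.items()]
    prods = [(sid, species_index[sid], c) for sid, c in reaction.products.items()]

    # modifier terms are shared by every template
    mods: list[tuple[int, str, float]] = []
    for mod in reaction.modifiers:
        sid = mod["species"]
        mode = mod["mode"]
        role = ("Ka." if mode == "activator" else "Ki.") + sid
        mods.append((species_index[sid], mode, _p(params, pm, role, rid)))

    def _modifier_factor(c: np.ndarray) -> float:
        f = 1.0
        for idx, mode, k in mods:
            m = c[idx] if c[idx] > 0.0 else 0.0
            f *= m / (k + m) if mode == "activator" else k / (k + m)
        return f

    if tmpl == "irreversible_mm":
        km = [_p(params, pm, f"Km.{sid}", rid) for sid, _, _ in subs]
        hill = [
            float(params[pm[f"n.{sid}"]]) if f"n.{sid}" in pm else 1.0
            for sid, _, _ in subs
        ]
        kp = [
            (idx, _p(params, pm, f"Kp.{sid}", rid))
            for sid, idx, _ in prods
            if f"Kp.{sid}" in pm
        ]
        vf = _p(params, pm, "Vf", rid)

        def rate(c: np.ndarray) -> float:
            v = vf
            for (sid, idx, coeff), k, n in zip(subs, km, hill):
                s = c[idx] if c[idx] > 0.0 else 0.0
                x = (s / k) ** n
                v *= (x / (1.0 + x)) ** coeff
            if kp:
                pden = 1.0
                for idx, k in kp:
                    p = c[idx] if c[idx] > 0.0 else 0.0
                    pden += p / k
                v /= pden
            return v * _modifier_factor(c)

        return rate

    if tmpl == "reversible_mm":
        vf = _p(params, pm, "Vf", rid)
        if rl.constrained:
            keq = _p(params, pm, "Keq", rid)
            vr = vf / keq
        else:
            vr = _p(params, pm, "Vr", rid)
        km_s = [_p(params, pm, f"Km.{sid}", rid) for sid, _, _ in subs]
        km_p = [_p(params, pm, f"Km.{sid}", rid) for sid, _, _ in prods]
        # optional dead-end cross-binding terms Kx.<sub>.<prod>
        cross = []
        for (ssid, sidx, _), ks in zip(subs, km_s):
            for (psid, pidx, _), kpp in zip(prods, km_p):
                role = f"Kx.{ssid}.{psid}"
                if role in pm:
                    cross.append((sidx, ks, pidx, kpp, _p(params, pm, role, rid)))
        scale = 1.0
        for (_, _, coeff), k in zip(subs, km_s):
            scale *= k ** coeff

        def rate(c: np.ndarray) -> float:
            fwd = vf
            den_s = 1.0
            for (sid, idx, coeff), k in zip(subs, km_s):
                s = c[idx] if c[idx] > 0.0 else 0.0
                fwd *= s ** coeff
                den_s *= (1.0 + s / k) ** coeff
            rev = vr
            den_p = 1.0
            for (sid, idx, coeff), k in zip(prods, km_p):
                p = c[idx] if c[idx] > 0.0 else 0.0
                rev *= p ** coeff
                den_p *= (1.0 + p / k) ** coeff
            den = den_s + den_p - 1.0
            for si, ks, pi, kpp, kx in cross:
                s = c[si] if c[si] > 0.0 else 0.0
                p = c[pi] if c[pi] > 0.0 else 0.0
                den += (s / ks) * (p / kpp) / kx
            return (fwd - rev) / scale / den * _modifier_factor(c)

        return rate

    if tmpl == "facilitated_transport":
        if len(subs) != 1 or len(prods) != 1:
            raise RateLawError(f"reaction {rid!r}: facilitated transport needs 1 substrate, 1 product")
        vf = _p(params, pm, "Vf", rid)
        km = _p(params, pm, "Km", rid)
        iso, isi = subs[0][1], prods[0][1]

        def rate(c: np.ndarray) -> float:
            so = c[iso] if c[iso] > 0.0 else 0.0
            si = c[isi] if c[isi] > 0.0 else 0.0
            return vf * (so - si) / (km + so + si) * _modifier_factor(c)

        return rate

    if tmpl == "transport_rev":
        if len(subs) != 1 or len(prods) != 1:
            raise RateLawError(f"reaction {rid!r}: transport needs 1 substrate, 1 product")
        vf = _p(params, pm, "Vf", rid)
        vr = _p(params, pm, "Vr", rid)
        km_o = _p(params, pm, "Km_out", rid)
        km_i = _p(params, pm, "Km_in", rid)
        iso, isi = subs[0][1], prods[0][1]

        def rate(c: np.ndarray) -> float:
            so = c[iso] if c[iso] > 0.0 else 0.0
            si = c[isi] if c[isi] > 0.0 else 0.0
            return (vf * so / (km_o + so) - vr * si / (km_i + si)) * _modifier_factor(c)

        return rate

    if tmpl == "mass_action":
        kf = _p(params, pm, "kf", rid)
        kr = float(params[pm["kr"]]) if "kr" in pm else 0.0

        def rate(c: np.ndarray) -> float:
            fwd = kf
            for _, idx, coeff in subs:
                s = c[idx] if c[idx] > 0.0 else 0.0
                fwd *= s ** coeff
            rev = 0.0
            if kr:
                rev = kr
                for _, idx, coeff in prods:
                    p = c[idx] if c[idx] > 0.0 else 0.0
                    rev *= p ** coeff
            return (fwd - rev) * _modifier_factor(c)

        return rate

    raise RateLawError(f"unhandled template {tmpl!r}")


def reaction_rate(reaction, state: Mapping[str, float], params: Mapping[str, float]) -> float:
    """Evaluate one reaction rate at a concentration state (mM/min).

    ``state`` maps species id -> concentration (mM); all species that the
    reaction touches (including modifiers) must be present and >= 0 up to
    solver round-off.
    """
    ids = list(state.keys())
    index = {s: i for i, s in enumerate(ids)}
    conc = np.array([state[s] for s in ids], dtype=float)
    if conc.size and conc.min() < -1e-9:
        bad = ids[int(np.argmin(conc))]
        raise ValueError(f"negative concentration for {bad}: {conc.min()}")
    return compile_rate(reaction, index, params)(conc)
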