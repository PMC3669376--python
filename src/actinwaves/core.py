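"""Reaction and flux right-hand sides of the continuum actin-wave model.

The model couples three layers:

* cytosolic fields on the (x, z) cross-section: pointed-end densities of the
  three filament types (free ``p``, Arp2/3-capped ``r``, coronin-capped
  ``c``) that are advected along z, and diffusible G-actin, Arp2/3, coronin
  and Rac (inactive/active);
* a membrane ODE layer at z = 0: membrane-bound G-actin, the WASP cycle
  (W -> W* -> WA -> WAG) that assembles the branching complex, and
  short filaments of length <= 2 whose kinetics differ from the continuum;
* an algebraically eliminated length-3 filament pool whose elongation flux
  supplies the z = 0 boundary condition of the continuum filament fields.

Everything here is a pure function returning rates/fluxes; time stepping
lives in :mod:`actinwaves.engine`.  Fluxes returned for cytosolic fields are
surface fluxes in uM*um/s, positive into the cytosol.
"""

from __future__ import annotations

import numpy as np

from .params import GridSpec, ModelParams
from .state import BarbedEndDensity, CytosolState, MembraneState

__all__ = [
    "elongation_speeds",
    "bulk_reaction_rates",
    "membrane_layer_rates",
    "short_filament_closure",
    "conservation_corrections",
    "total_barbed_ends",
]


def elongation_speeds(g_m, params: ModelParams):
    """Advection speeds (um/s) of the filament fields, per x.

    Barbed ends polymerize at the membrane at ``v_poly * g_m`` and free
    pointed ends depolymerize at ``v_depoly``, so Arp2/3- and coronin-capped
    filaments (protected pointed ends) advect at ``v_capped = v_poly*g_m``
    while free filaments advect at ``v_free = v_capped - v_depoly``.  Both
    are uniform in z at fixed x because barbed ends sit at the interface.
    """
    g_m = np.asarray(g_m, dtype=float)
    if np.any(g_m < 0):
        raise ValueError("membrane G-actin density g_m must be non-negative")
    v_capped = params.v_poly * g_m
    v_free = v_capped - params.v_depoly
    return v_capped, v_free


def bulk_reaction_rates(state: CytosolState, params: ModelParams,
                        include_depoly_source: bool = True) -> dict:
    """Pointwise bulk reaction contributions, per cytosolic field (uM/s).

    Coronin binding converts Arp2/3-capped ends to coronin-capped ends
    (releasing Arp2/3 one-for-one); debranching converts coronin-capped ends
    to free ends (releasing coronin); Rac interconverts by spontaneous
    activation and deactivation.  The depolymerization monomer source
    ``(v_depoly/delta) * p`` for G-actin can be excluded when the caller
    accounts for it inside a conservative transport kernel.
    """
    shapes = {f.shape for _, f in state.items()}
    if len(shapes) != 1:
        raise ValueError(f"cytosol fields have mismatched shapes: {shapes}")
    conv_rc = params.k_cor * state.cor * state.r          # r -> c, cor consumed
    conv_cp = params.k_debranch * state.c                 # c -> p, cor released
    conv_rp = params.k_debranch_r * state.r               # r -> p, arp released
    rac_fwd = params.k_rac_spont * state.rac
    rac_back = params.k_rac_deact * state.rac_star
    zeros = np.zeros_like(state.p)
    rates = {
        "p": conv_cp + conv_rp,
        "r": -conv_rc - conv_rp,
        "c": conv_rc - conv_cp,
        "g": (params.v_depoly / params.delta) * state.p
             if include_depoly_source else zeros,
        "arp": conv_rc + conv_rp,
        "cor": conv_cp - conv_rc,
        "rac": rac_back - rac_fwd,
        "rac_star": rac_fwd - rac_back,
    }
    return rates


def traces_at_membrane(state: CytosolState) -> dict:
    return {n: f[:, 0] for n, f in state.items()}


def membrane_layer_rates(mem: MembraneState, traces: dict, B: BarbedEndDensity,
                         params: ModelParams, pten_mask=None,
                         b_polymerizing=None, k_dim_eff=None):
    """Membrane ODE right-hand sides and boundary fluxes for the cytosol.

    Implements, per x: Rac activation by barbed ends (zeroed where
    ``pten_mask`` is set — the PTEN surrogate), the WASP activation cycle,
    Arp2/3 and G-actin recruitment into the branching complex, branching
    (WAG + barbed end -> new length-1 Arp2/3-capped filament), G-actin
    membrane exchange, dimerization into length-2 free filaments, and the
    polymerization drain on membrane G-actin.

    ``b_polymerizing`` optionally restricts the drain to a subset of barbed
    ends (the engine charges the continuum-filament share of the drain inside
    its transport kernel, paired with the same upwind fluxes); by default the
    full ``k_poly * g_m * B`` drain is applied here.

    Returns ``(mem_rates, boundary_fluxes)``: dicts keyed by membrane and
    cytosolic field names.  The four WASP rates sum to zero.
    """
    b = np.asarray(B.B, dtype=float)
    nx = mem.g_m.shape[0]
    if b.shape[0] != nx:
        raise ValueError("B resolution does not match membrane state")
    for name in ("g", "arp", "cor", "rac", "rac_star"):
        if traces[name].shape[0] != nx:
            raise ValueError(f"trace {name!r} resolution mismatch")
        if np.any(traces[name] < 0):
            raise ValueError(f"negative membrane trace for {name!r}")
    if np.any(mem.g_m < 0) or np.any(b < 0):
        raise ValueError("negative membrane density")
    if pten_mask is None:
        pten_mask = np.zeros(nx, dtype=bool)
    pten_mask = np.asarray(pten_mask)
    if pten_mask.shape[0] != nx:
        raise ValueError("pten_mask length does not match membrane resolution")
    if k_dim_eff is None:
        k_dim_eff = params.k_dim
    drain_ends = b if b_polymerizing is None else np.asarray(b_polymerizing)

    ra = params.k_rac_act * b * traces["rac"]
    ra = np.where(pten_mask, 0.0, ra)
    wa = params.k_wasp_act * traces["rac_star"] * mem.W
    wd = params.k_wasp_deact * mem.W_star
    aon = params.k_arp_on * traces["arp"] * mem.W_star
    aoff = params.k_arp_off * mem.WA
    gon = params.k_gact_on * mem.g_m * mem.WA
    goff = params.k_gact_off * mem.WAG
    br = params.k_branch * mem.WAG * b
    gmon = params.k_gm_on * traces["g"]
    gmoff = params.k_gm_off * mem.g_m
    dim = k_dim_eff * mem.g_m ** 2
    drain = params.k_poly * mem.g_m * drain_ends

    zeros = np.zeros(nx)
    mem_rates = {
        "W": -wa + wd + (0.0 if params.branch_returns_wasp_active else br),
        "W_star": wa - wd - aon + aoff
                  + (br if params.branch_returns_wasp_active else 0.0),
        "WA": aon - aoff - gon + goff,
        "WAG": gon - goff - br,
        "g_m": gmon - gmoff - 2.0 * dim - gon + goff - drain,
        "s_p1": zeros,
        "s_p2": dim,
        "s_r1": br,
        "s_r2": zeros,
        "s_c1": zeros,
        "s_c2": zeros,
    }
    boundary_fluxes = {
        "p": zeros, "r": zeros, "c": zeros,
        "g": -gmon + gmoff,
        "arp": -aon + aoff,
        "cor": zeros,
        "rac": -ra,
        "rac_star": ra,
    }
    return mem_rates, boundary_fluxes


def short_filament_closure(mem: MembraneState, v_capped, v_free,
                           params: ModelParams, p_bottom=None, cor0=None):
    """Short-filament (length <= 2) kinetics and the length-3 closure.

    Length-1 and length-2 filaments evolve as membrane pools: elongation
    moves them up the length ladder at the per-filament rate
    ``lam = v_capped/delta`` (free filaments additionally depolymerize at
    ``mu = (v_capped - v_free)/delta``); dimer dissociation destroys length-2
    free filaments, returning both subunits to membrane G-actin; debranching
    destroys length-1 branches.  The length-3 pool is eliminated by its
    pseudo-steady balance and its net elongation flux becomes the z = 0
    inflow of the continuum fields, while downward advection of continuum
    free filaments (``J_p``) re-enters the pool.  Coronin binding and
    debranching of the length-3 pool are neglected.

    Returns ``(rates, fluxes, aux)`` where ``rates`` holds d/dt of the pools
    plus the G-actin releases credited to ``g_m``; ``fluxes`` are z = 0
    boundary fluxes for the cytosolic fields (uM*um/s, positive into the
    cytosol); ``aux`` carries the pseudo-steady pools and transition fluxes.
    """
    v_capped = np.asarray(v_capped, dtype=float)
    v_free = np.asarray(v_free, dtype=float)
    nx = mem.g_m.shape[0]
    if p_bottom is None:
        p_bottom = np.zeros(nx)
    if cor0 is None:
        cor0 = np.zeros(nx)
    for pool in ("s_p1", "s_p2", "s_r1", "s_r2", "s_c1", "s_c2"):
        if np.any(getattr(mem, pool) < -1e-9):
            raise FloatingPointError(f"negative short-filament pool {pool}")

    lam = np.maximum(v_capped, 0.0) / params.delta
    mu = np.maximum(v_capped - v_free, 0.0) / params.delta

    # pseudo-steady length-3 pools; for capped types the balance
    # lam*s2_in = lam*out gives pool == s2 identically
    J_p = np.maximum(-v_free, 0.0) * np.asarray(p_bottom)
    denom = lam + mu
    with np.errstate(divide="ignore", invalid="ignore"):
        p3 = np.where(denom > 0.0, (lam * mem.s_p2 + J_p) / np.where(denom > 0, denom, 1.0), 0.0)
    r3 = mem.s_r2.copy()
    c3 = mem.s_c2.copy()
    T_p = lam * p3
    T_r = lam * r3
    T_c = lam * c3

    kcor = params.k_cor if params.short_pool_coronin else 0.0
    corbind1 = kcor * cor0 * mem.s_r1
    corbind2 = kcor * cor0 * mem.s_r2
    db1_c = params.k_debranch * mem.s_c1          # destroys, subunit -> g_m
    db2_c = params.k_debranch * mem.s_c2          # -> free dimer s_p2
    db1_r = params.k_debranch_r * mem.s_r1
    db2_r = params.k_debranch_r * mem.s_r2

    rates = {
        "s_p1": -(lam + mu) * mem.s_p1,
        "s_p2": lam * mem.s_p1 + mu * p3 + db2_c + db2_r - (lam + mu) * mem.s_p2,
        "s_r1": -lam * mem.s_r1 - corbind1 - db1_r,
        "s_r2": lam * mem.s_r1 - lam * mem.s_r2 - corbind2 - db2_r,
        "s_c1": corbind1 - lam * mem.s_c1 - db1_c,
        "s_c2": corbind2 + lam * mem.s_c1 - lam * mem.s_c2 - db2_c,
        # G-actin released to the membrane pool: pointed-end loss of short
        # free filaments, dimer dissociation (2 subunits), the length-3
        # depolymerization step, and destroyed length-1 branches
        "g_m": mu * mem.s_p1 + 2.0 * mu * mem.s_p2 + mu * p3 + db1_c + db1_r,
    }
    zeros = np.zeros(nx)
    fluxes = {
        "p": T_p - J_p,
        "r": T_r,
        "c": T_c,
        "g": zeros,
        "arp": corbind1 + corbind2 + db1_r + db2_r,
        "cor": db1_c + db2_c - corbind1 - corbind2,
        "rac": zeros,
        "rac_star": zeros,
    }
    aux = {"p3": p3, "r3": r3, "c3": c3, "T_p": T_p, "T_r": T_r, "T_c": T_c,
           "J_p": J_p, "lam": lam, "mu": mu}
    return rates, fluxes, aux


def total_barbed_ends(state: CytosolState, mem: MembraneState, grid: GridSpec,
                      params: ModelParams) -> BarbedEndDensity:
    """Total barbed-end surface density B(x), in uM*um.

    Column integral of all continuum pointed-end densities plus the
    length-1/2 membrane pools plus the pseudo-steady length-3 amount.
    """
    b_cont = (state.p + state.r + state.c).sum(axis=1) * grid.dz
    v_capped, v_free = elongation_speeds(mem.g_m, params)
    _, _, aux = short_filament_closure(
        mem, v_capped, v_free, params, p_bottom=state.p[:, 0],
        cor0=state.cor[:, 0])
    B = (b_cont + mem.s_p1 + mem.s_p2 + mem.s_r1 + mem.s_r2
         + mem.s_c1 + mem.s_c2 + aux["p3"] + aux["r3"] + aux["c3"])
    return BarbedEndDensity(B=B)


def conservation_corrections(state: CytosolState, mem: MembraneState,
                             grid: GridSpec, params: ModelParams) -> dict:
    """Corrective G-actin sources closing the monomer ledger, per x.

    Two bookkeeping errors of the continuum reduction are offset so the
    global actin budget is constant in a closed domain:

    * the stabilizing diffusion ``nu = delta*|v|/2`` in each filament
      equation changes the z-weighted subunit content of a column by
      ``(nu/delta)*(tau_bottom - tau_top)`` without touching G-actin;
    * the pseudo-steady length-3 elimination exchanges filaments with the
      continuum at z = 0: a filament entering the bottom cell (centre
      ``z0 = dz/2``) instantly represents ``z0/delta`` subunits while the
      pool and membrane supplied 4, so each 3->4 transition is charged
      ``4 - z0/delta`` to G-actin and each 4->3 re-entry returns
      ``z0/delta - 3`` (its depolymerization release included).

    Returns a dict with the net boundary flux ``g_flux`` (uM*um/s, positive
    into the cytosol at z = 0) and its two components.
    """
    v_capped, v_free = elongation_speeds(mem.g_m, params)
    _, _, aux = short_filament_closure(
        mem, v_capped, v_free, params, p_bottom=state.p[:, 0],
        cor0=state.cor[:, 0])
    z0 = grid.dz / 2.0
    d = params.delta
    transition = ((4.0 - z0 / d) * (aux["T_p"] + aux["T_r"] + aux["T_c"])
                  + (z0 / d - 3.0) * aux["J_p"])
    stab = np.zeros(mem.g_m.shape[0])
    for fld, v in (("p", v_free), ("r", v_capped), ("c", v_capped)):
        nu = d * np.abs(v) / 2.0
        a = getattr(state, fld)
        stab -= (nu / d) * (a[:, 0] - a[:, -1])
    return {"g_flux": transition + stab, "transition": transition,
            "stabilizing": stab}
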