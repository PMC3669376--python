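"""Time integration of the full 2-D actin-wave model.

The step is an operator splitting: a half-step of reactions (bulk
conversions plus the membrane ODE layer with its boundary exchanges), a full
step of conservative transport (upwind advection of the filament fields
along z paired with the matching membrane G-actin drain and depolymerization
release), a full step of implicit diffusion of the cytosolic species, and a
closing reaction half-step.  Every sub-step moves matter stoichiometrically
between pools, so the four global budgets (actin, Arp2/3, coronin, Rac) are
conserved to accumulation round-off in a closed domain; accuracy, not
conservation, is what depends on dt.

Stiff pieces are handled inside the sub-steps: the short-filament ladder is
integrated with exact exponential updates per sub-interval (its per-filament
elongation/depolymerization rates v/delta are orders of magnitude above the
signalling rates), and the membrane drain of G-actin by polymerization is
sub-stepped adaptively so the pool cannot be overdrawn.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.linalg import solve_banded

from .core import bulk_reaction_rates, elongation_speeds
from .params import GridSpec, ModelParams
from .state import CYTOSOL_FIELDS, CytosolState, MembraneState, initial_state

__all__ = [
    "StimulusProtocol", "PTENRegion", "SimulationConfig", "Trajectory",
    "advect_filaments", "diffuse_cytosol", "Simulator", "run",
    "SolverError", "StepSizeError",
]


class SolverError(RuntimeError):
    """Raised when the solution leaves the physical regime (NaN, blow-up)."""


class StepSizeError(ValueError):
    """Raised when dt violates a stability bound (CFL or diffusion number)."""


# --------------------------------------------------------------------------
# protocols and configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Transient local increase of the dimerization rate constant.

    Emulates an actin-wave precursor (e.g. a clathrin-coated structure):
    inside [x0, x1] on the membrane, k_dim is multiplied by ``fold`` from
    ``start`` for ``duration`` seconds.
    """

    x0: float
    x1: float
    start: float = 0.0
    duration: float = 20.0
    fold: float = 50.0

    def __post_init__(self):
        if not (self.x1 > self.x0):
            raise ValueError("stimulus interval must have x1 > x0")
        if self.fold < 1.0:
            raise ValueError("stimulus fold-increase must be >= 1")
        if self.duration < 0 or self.start < 0:
            raise ValueError("stimulus timing must be non-negative")

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PTENRegion:
    """Membrane interval where barbed-end-driven Rac activation is disabled.

    The region appears at ``onset``, stays stationary until ``move_start``
    (defaults to onset) and thereafter translates at a signed ``speed``; it
    is snapped to the nearest grid cells (no partial-cell weighting).
    """

    x0: float
    x1: float
    onset: float = 0.0
    speed: float = 0.0
    move_start: float | None = None

    def __post_init__(self):
        if not (self.x1 > self.x0):
            raise ValueError("PTEN interval must have x1 > x0")
        if self.move_start is None:
            object.__setattr__(self, "move_start", self.onset)

    def interval(self, t: float):
        if t < self.onset:
            return None
        shift = self.speed * max(0.0, t - self.move_start)
        return self.x0 + shift, self.x1 + shift

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class SimulationConfig:
    """Everything that determines a run; serializable and deterministic."""

    params: ModelParams = dfield(default_factory=ModelParams)
    grid: GridSpec = dfield(default_factory=GridSpec)
    stimuli: list = dfield(default_factory=list)
    pten_regions: list = dfield(default_factory=list)
    t_end: float = 150.0
    output_every: float = 2.0
    seed: int | None = None
    noise_amplitude: float = 0.0
    tirf_depth: float = 0.2       #: TIRF integration depth (um)
    label: str = ""

    def validate(self):
        self.params.validate()
        for s in self.stimuli:
            if s.x0 < 0 or s.x1 > self.grid.Lx:
                raise ValueError("stimulus interval outside the domain")
        if self.t_end <= 0 or self.output_every <= 0:
            raise ValueError("t_end and output_every must be positive")
        if not (0 < self.tirf_depth <= self.grid.Lz):
            raise ValueError("tirf_depth must lie in (0, Lz]")

    def to_dict(self):
        return {
            "params": self.params.to_dict(),
            "grid": self.grid.to_dict(),
            "stimuli": [s.to_dict() for s in self.stimuli],
            "pten_regions": [p.to_dict() for p in self.pten_regions],
            "t_end": self.t_end,
            "output_every": self.output_every,
            "seed": self.seed,
            "noise_amplitude": self.noise_amplitude,
            "tirf_depth": self.tirf_depth,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {"params", "grid", "stimuli", "pten_regions", "t_end",
                 "output_every", "seed", "noise_amplitude", "tirf_depth",
                 "label"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kw = dict(d)
        kw["params"] = ModelParams.from_dict(d.get("params", {}))
        kw["grid"] = GridSpec.from_dict(d.get("grid", {}))
        kw["stimuli"] = [StimulusProtocol(**s) for s in d.get("stimuli", [])]
        kw["pten_regions"] = [PTENRegion(**p) for p in d.get("pten_regions", [])]
        cfg = cls(**kw)
        cfg.validate()
        return cfg


# --------------------------------------------------------------------------
# transport and diffusion kernels
# --------------------------------------------------------------------------

def advect_filaments(field, speed, dt, grid: GridSpec, stabilizing=True,
                     periodic=False):
    """First-order upwind transport along z with per-column speed.

    Conservative flux form with closed end faces (periodic in test mode);
    optional explicit stabilizing diffusion with coefficient delta*|v|/2 is
    applied by the caller via :func:`stabilizing_diffusion` — here
    ``stabilizing`` only toggles the CFL check message.  Returns
    ``(new_field, info)`` where ``info`` contains the per-column sum of the
    upwind cells actually transported (``upwind_sum``, uM*um) used to pair
    monomer exchange with the realized fluxes.
    """
    field = np.asarray(field, dtype=float)
    v = np.broadcast_to(np.asarray(speed, dtype=float), field.shape[:1])
    dz = grid.dz
    cfl = np.max(np.abs(v)) * dt / dz
    if cfl > 1.0 + 1e-12:
        raise StepSizeError(f"advection CFL {cfl:.3f} exceeds 1")
    nz = field.shape[1]
    pos = (v > 0)[:, None]
    if periodic:
        up = np.where(pos, np.roll(field, 1, axis=1), field)
        flux_lo = v[:, None] * up                     # flux through lower faces
        flux_hi = np.roll(flux_lo, -1, axis=1)
        new = field - dt / dz * (flux_hi - flux_lo)
        info = {"upwind_sum": field.sum(axis=1) * dz}
        return new, info
    # interior faces j = 1..nz-1; closed at j = 0 and j = nz
    upwind = np.where(pos, field[:, :-1], field[:, 1:])
    flux = v[:, None] * upwind                        # shape (nx, nz-1)
    new = field.copy()
    new[:, :-1] -= dt / dz * flux
    new[:, 1:] += dt / dz * flux
    upwind_sum = np.where(v > 0, field[:, :-1].sum(axis=1),
                          field[:, 1:].sum(axis=1)) * dz
    info = {"upwind_sum": upwind_sum}
    return new, info


def stabilizing_diffusion(field, nu, dt, grid: GridSpec):
    """Explicit second-difference smoothing in z with no-flux ends.

    ``nu`` is per-column (delta*|v|/2).  Returns the new field; pointed-end
    number per column is unchanged.
    """
    dz = grid.dz
    r = np.asarray(nu, dtype=float)[:, None] * dt / dz ** 2
    if np.max(r) > 0.5 + 1e-12:
        raise StepSizeError("stabilizing-diffusion number exceeds 1/2")
    lap = np.zeros_like(field)
    lap[:, 1:-1] = field[:, 2:] - 2 * field[:, 1:-1] + field[:, :-2]
    lap[:, 0] = field[:, 1] - field[:, 0]
    lap[:, -1] = field[:, -2] - field[:, -1]
    return field + r * lap


def _banded_matrix(n: int, alpha: float):
    """Banded (I + alpha*A) for the 1-D Neumann FV Laplacian, ab-format."""
    ab = np.zeros((3, n))
    ab[0, 1:] = -alpha
    ab[2, :-1] = -alpha
    ab[1, :] = 1.0 + 2.0 * alpha
    ab[1, 0] -= alpha
    ab[1, -1] -= alpha
    return ab


def diffuse_cytosol(field, D, dt, grid: GridSpec, boundary_flux=None,
                    _cache=None):
    """Conservative implicit diffusion on the (x, z) grid.

    Dimensionally split backward-Euler solves (x sweep then z sweep) with
    no-flux walls; a prescribed flux at the z = 0 face (uM*um/s, positive
    into the domain) is deposited into the bottom cell row beforehand.
    Unconditionally stable and positivity preserving; total mass changes by
    exactly the integrated boundary flux.
    """
    field = np.asarray(field, dtype=float)
    nx, nz = field.shape
    if boundary_flux is not None:
        field = field.copy()
        field[:, 0] += dt * np.asarray(boundary_flux) / grid.dz
    if D == 0.0 or dt == 0.0:
        return field
    key = (D, dt, nx, nz, grid.dx, grid.dz)
    if _cache is not None and key in _cache:
        ab_x, ab_z = _cache[key]
    else:
        ab_x = _banded_matrix(nx, D * dt / grid.dx ** 2) if nx > 1 else None
        ab_z = _banded_matrix(nz, D * dt / grid.dz ** 2)
        if _cache is not None:
            _cache[key] = (ab_x, ab_z)
    if ab_x is not None:
        field = solve_banded((1, 1), ab_x, field, overwrite_b=False)
    field = solve_banded((1, 1), ab_z, field.T, overwrite_b=False).T
    return field


def _diffuse_membrane_1d(arr, D, dt, grid: GridSpec, _cache):
    if D == 0.0 or grid.nx == 1:
        return arr
    key = ("mem", D, dt, grid.nx, grid.dx)
    if key not in _cache:
        _cache[key] = _banded_matrix(grid.nx, D * dt / grid.dx ** 2)
    return solve_banded((1, 1), _cache[key], arr)


# --------------------------------------------------------------------------
# the simulator
# --------------------------------------------------------------------------

def _exp_pool_update(s, loss_rate, source_rate, dt):
    """Exact update of ds/dt = source - loss_rate*s over dt.

    Returns (s_new, outflux_total) with outflux_total = integral of
    loss_rate*s dt, so that mass balances exactly:
    s_new = s + source*dt - outflux_total.
    """
    a = np.asarray(loss_rate, dtype=float)
    src = np.asarray(source_rate, dtype=float)
    small = a * dt < 1e-12
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        E = np.exp(-a * dt)
        s_new = np.where(small, s + src * dt,
                         s * E + np.where(a > 0, src / np.where(a > 0, a, 1.0), 0.0)
                         * (1.0 - E))
    out = s + src * dt - s_new
    return s_new, np.maximum(out, 0.0)


class Simulator:
    """Stateful stepper for a :class:`SimulationConfig`.

    Holds solver caches; :meth:`step` advances (state, mem) by one dt.
    """

    #: fraction of a pool a single explicit exchange may consume
    MAX_TAKE = 0.9

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.params = config.params
        self.grid = config.grid
        self._cache: dict = {}
        self.clamped_mass = 0.0       # |mass| zeroed by the negativity clamp
        self.n_clamp_events = 0
        x = self.grid.x_centers
        self._x_centers = x

    # -- protocol masks ----------------------------------------------------
    def k_dim_eff(self, t: float):
        k = np.full(self.grid.nx, self.params.k_dim)
        for s in self.config.stimuli:
            if s.active(t):
                mask = (self._x_centers >= s.x0) & (self._x_centers < s.x1)
                k[mask] = self.params.k_dim * s.fold
        return k

    def pten_mask(self, t: float):
        mask = np.zeros(self.grid.nx, dtype=bool)
        for reg in self.config.pten_regions:
            iv = reg.interval(t)
            if iv is None:
                continue
            a, b = iv
            mask |= (self._x_centers >= a) & (self._x_centers < b)
        return mask

    # -- initial condition -------------------------------------------------
    def initial(self):
        state, mem = initial_state(self.grid, self.params)
        if self.config.noise_amplitude > 0.0:
            rng = np.random.default_rng(self.config.seed or 0)
            pert = 1.0 + self.config.noise_amplitude * rng.standard_normal(
                (self.grid.nx, self.grid.nz))
            state.g *= np.clip(pert, 0.0, None)
        return state, mem

    # -- reaction half-step --------------------------------------------------
    def _bulk_reactions(self, state: CytosolState, dt: float):
        """Explicit, flux-limited bulk conversions and Rac interconversion."""
        p_ = self.params
        take = self.MAX_TAKE
        conv_rc = np.minimum(p_.k_cor * state.cor * state.r * dt,
                             take * np.minimum(state.r, state.cor))
        conv_cp = np.minimum(p_.k_debranch * state.c * dt, take * state.c)
        conv_rp = np.minimum(p_.k_debranch_r * state.r * dt, take * state.r) \
            if p_.k_debranch_r else 0.0
        act = np.minimum(p_.k_rac_spont * state.rac * dt, take * state.rac)
        deact = np.minimum(p_.k_rac_deact * state.rac_star * dt,
                           take * state.rac_star)
        state.r += -conv_rc - conv_rp
        state.c += conv_rc - conv_cp
        state.p += conv_cp + conv_rp
        state.arp += conv_rc + conv_rp
        state.cor += conv_cp - conv_rc
        state.rac += deact - act
        state.rac_star += act - deact

    def _membrane_phase(self, state: CytosolState, mem: MembraneState,
                        t: float, dt: float):
        """Membrane ODE layer + boundary exchanges, adaptively sub-stepped."""
        p_ = self.params
        dz = self.grid.dz
        k_dim_eff = self.k_dim_eff(t)
        pten = self.pten_mask(t)

        # sub-step count from the moderate (signalling / trace-depletion)
        # rates; the short-filament ladder is integrated exactly below and
        # does not constrain dt
        b_est = ((state.p + state.r + state.c).sum(axis=1) * dz
                 + mem.s_p1 + mem.s_p2 + mem.s_r1 + mem.s_r2
                 + mem.s_c1 + mem.s_c2).max()
        rate = max(
            p_.k_wasp_act * float(state.rac_star[:, 0].max(initial=0.0)),
            p_.k_wasp_deact, p_.k_arp_off, p_.k_gact_off,
            p_.k_arp_on * float(state.arp[:, 0].max(initial=0.0)),
            p_.k_gact_on * float(mem.g_m.max(initial=0.0)),
            p_.k_branch * b_est,
            p_.k_rac_act * b_est / dz,
            p_.k_gm_on / dz, p_.k_gm_off,
            p_.k_debranch, 1e-12,
            # membrane-pool polymerization drain on g_m
            p_.v_poly / p_.delta * float(
                (mem.s_p1 + mem.s_p2 + mem.s_r1 + mem.s_r2
                 + mem.s_c1 + mem.s_c2).max(initial=0.0)),
        )
        n_sub = int(np.clip(np.ceil(dt * rate / 0.25), 1, 200))
        dts = dt / n_sub
        for _ in range(n_sub):
            self._membrane_substep(state, mem, dts, k_dim_eff, pten)

    def _membrane_substep(self, state: CytosolState, mem: MembraneState,
                          dt: float, k_dim_eff, pten):
        p_ = self.params
        dz = self.grid.dz
        z0 = dz / 2.0
        take = self.MAX_TAKE
        g0 = state.g[:, 0]
        arp0 = state.arp[:, 0]
        cor0 = state.cor[:, 0]
        rac0 = state.rac[:, 0]
        racs0 = state.rac_star[:, 0]
        p0 = state.p[:, 0]

        v_c, v_f = elongation_speeds(mem.g_m, p_)
        lam = np.maximum(v_c, 0.0) / p_.delta
        mu = p_.v_depoly / p_.delta

        # length-3 closure (frozen over the sub-step)
        J_rate = np.maximum(-v_f, 0.0) * p0
        denom = lam + mu
        p3 = np.where(denom > 0, (lam * mem.s_p2 + J_rate)
                      / np.where(denom > 0, denom, 1.0), 0.0)
        r3, c3 = mem.s_r2, mem.s_c2
        b_cont = (state.p + state.r + state.c).sum(axis=1) * dz
        pools = (mem.s_p1 + mem.s_p2 + mem.s_r1 + mem.s_r2
                 + mem.s_c1 + mem.s_c2)
        B = b_cont + pools + p3 + r3 + c3

        # --- signalling amounts (explicit, flux-limited, uM*um) -------------
        d_ra = np.where(pten, 0.0,
                        np.minimum(p_.k_rac_act * B * rac0 * dt,
                                   take * rac0 * dz))
        d_wa = np.minimum(p_.k_wasp_act * racs0 * mem.W * dt, take * mem.W)
        d_wd = np.minimum(p_.k_wasp_deact * mem.W_star * dt, take * mem.W_star)
        d_aon = np.minimum(p_.k_arp_on * arp0 * mem.W_star * dt,
                           np.minimum(take * arp0 * dz, take * mem.W_star))
        d_aoff = np.minimum(p_.k_arp_off * mem.WA * dt, take * mem.WA)
        d_gon = np.minimum(p_.k_gact_on * mem.g_m * mem.WA * dt,
                           np.minimum(take * mem.g_m, take * mem.WA))
        d_goff = np.minimum(p_.k_gact_off * mem.WAG * dt, take * mem.WAG)
        d_br = np.minimum(p_.k_branch * mem.WAG * B * dt, take * mem.WAG)
        d_gmon = np.minimum(p_.k_gm_on * g0 * dt, take * g0 * dz)
        d_gmoff = np.minimum(p_.k_gm_off * mem.g_m * dt, take * mem.g_m)
        d_dim = np.minimum(k_dim_eff * mem.g_m ** 2 * dt,
                           take * 0.5 * mem.g_m)

        # --- short-filament ladder: exact exponential updates ---------------
        kcorp = p_.k_cor if p_.short_pool_coronin else 0.0
        cb = kcorp * cor0
        kdbr = p_.k_debranch_r
        # r1: loss to elongation, coronin binding, spontaneous debranch
        a_r1 = lam + cb + kdbr
        s_r1n, out_r1 = _exp_pool_update(mem.s_r1, a_r1, d_br / dt, dt)
        share = np.where(a_r1 > 0, 1.0 / np.where(a_r1 > 0, a_r1, 1.0), 0.0)
        r1_elong = out_r1 * lam * share
        r1_cor = out_r1 * cb * share
        r1_dbr = out_r1 * kdbr * share
        # r2: fed by r1 elongation
        a_r2 = lam + cb + kdbr
        s_r2n, out_r2 = _exp_pool_update(mem.s_r2, a_r2, r1_elong / dt, dt)
        share = np.where(a_r2 > 0, 1.0 / np.where(a_r2 > 0, a_r2, 1.0), 0.0)
        r2_elong = out_r2 * lam * share         # -> length-3 -> continuum
        r2_cor = out_r2 * cb * share
        r2_dbr = out_r2 * kdbr * share
        # c1: fed by coronin binding on r1
        a_c1 = lam + p_.k_debranch
        s_c1n, out_c1 = _exp_pool_update(mem.s_c1, a_c1, r1_cor / dt, dt)
        share = np.where(a_c1 > 0, 1.0 / np.where(a_c1 > 0, a_c1, 1.0), 0.0)
        c1_elong = out_c1 * lam * share
        c1_db = out_c1 * p_.k_debranch * share  # destroyed, subunit -> g_m
        # c2
        a_c2 = lam + p_.k_debranch
        s_c2n, out_c2 = _exp_pool_update(mem.s_c2, a_c2,
                                         (r2_cor + c1_elong) / dt, dt)
        share = np.where(a_c2 > 0, 1.0 / np.where(a_c2 > 0, a_c2, 1.0), 0.0)
        c2_elong = out_c2 * lam * share
        c2_db = out_c2 * p_.k_debranch * share  # -> free dimer
        # p1 (no sources in the base model)
        a_p1 = lam + mu
        s_p1n, out_p1 = _exp_pool_update(mem.s_p1, a_p1, 0.0, dt)
        share = np.where(a_p1 > 0, 1.0 / np.where(a_p1 > 0, a_p1, 1.0), 0.0)
        p1_elong = out_p1 * lam * share
        p1_dep = out_p1 * mu * share            # subunit -> g_m, destroyed
        # p2: dimerization, p1 elongation, debranched dimers
        src_p2 = (d_dim + p1_elong + c2_db + r2_dbr) / dt
        a_p2 = lam + mu
        s_p2n, out_p2 = _exp_pool_update(mem.s_p2, a_p2, src_p2, dt)
        share = np.where(a_p2 > 0, 1.0 / np.where(a_p2 > 0, a_p2, 1.0), 0.0)
        p2_elong = out_p2 * lam * share         # -> length-3 conduit
        p2_dep = out_p2 * mu * share            # dimer dissociation: 2 -> g_m

        # The length-3 pool is a pseudo-steady conduit: it passes through
        # exactly what enters it this sub-step.  Capped filaments flow one
        # way (to the continuum); free filaments split between elongation to
        # the continuum (lam share) and depolymerization back to a dimer
        # plus one released monomer (mu share).
        d_J = np.minimum(J_rate * dt, take * p0 * dz)
        frac_lam = np.where(denom > 0, lam / np.where(denom > 0, denom, 1.0), 0.0)
        thru_p = p2_elong + d_J
        d_T_p = thru_p * frac_lam
        back_p = thru_p - d_T_p                 # -> s_p2 (+1 monomer to g_m)
        d_T_r = r2_elong
        d_T_c = c2_elong

        # --- apply ----------------------------------------------------------
        mem.W += -d_wa + d_wd + (0.0 if p_.branch_returns_wasp_active else d_br)
        mem.W_star += (d_wa - d_wd - d_aon + d_aoff
                       + (d_br if p_.branch_returns_wasp_active else 0.0))
        mem.WA += d_aon - d_aoff - d_gon + d_goff
        mem.WAG += d_gon - d_goff - d_br
        # g_m: exchange, complex loading, dimerization, ladder consumption
        # (1 subunit per realized elongation transition incl. the length-3
        # steps) and all depolymerization/debranch releases
        consumption = (r1_elong + r2_elong + c1_elong + c2_elong
                       + p1_elong + p2_elong + d_T_p + d_T_r + d_T_c)
        release = (p1_dep + 2.0 * p2_dep + back_p + c1_db + r1_dbr)
        mem.g_m += (d_gmon - d_gmoff - 2.0 * d_dim - d_gon + d_goff
                    - consumption + release)
        mem.s_r1, mem.s_r2 = s_r1n, s_r2n
        mem.s_c1, mem.s_c2 = s_c1n, s_c2n
        mem.s_p1, mem.s_p2 = s_p1n, s_p2n + back_p

        # cytosol boundary deposits (bottom cells)
        g0 += (-d_gmon + d_gmoff) / dz
        arp0 += (-d_aon + d_aoff + r1_cor + r2_cor + r1_dbr + r2_dbr) / dz
        cor0 += (c1_db + c2_db - r1_cor - r2_cor) / dz
        rac0 += -d_ra / dz
        racs0 += d_ra / dz
        state.p[:, 0] += (d_T_p - d_J) / dz
        state.r[:, 0] += d_T_r / dz
        state.c[:, 0] += d_T_c / dz
        # length-3 bookkeeping correction (see core.conservation_corrections)
        corr = ((4.0 - z0 / p_.delta) * (d_T_p + d_T_r + d_T_c)
                + (z0 / p_.delta - 3.0) * d_J)
        g0 += corr / dz

        if np.any(mem.g_m < 0):
            self._clamp(mem.g_m)

    # -- transport ---------------------------------------------------------
    def _transport(self, state: CytosolState, mem: MembraneState, dt: float):
        p_ = self.params
        grid = self.grid
        dz = grid.dz
        # adaptive sub-stepping so the polymerization drain cannot overdraw
        # g_m within a sub-interval
        b_cont = (state.p + state.r + state.c).sum(axis=1) * dz
        drain_rate = p_.v_poly / p_.delta * float(b_cont.max(initial=0.0))
        n_sub = int(np.clip(np.ceil(dt * drain_rate / 0.3), 1, 60))
        dts = dt / n_sub
        for _ in range(n_sub):
            self._transport_substep(state, mem, dts)

    def _transport_substep(self, state: CytosolState, mem: MembraneState,
                           dt: float):
        p_ = self.params
        grid = self.grid
        dz = grid.dz
        v_c, v_f = elongation_speeds(mem.g_m, p_)
        drain = np.zeros(grid.nx)
        corr = np.zeros(grid.nx)
        for name, v in (("p", v_f), ("r", v_c), ("c", v_c)):
            f = getattr(state, name)
            new, info = advect_filaments(f, v, dt, grid)
            # monomer exchange paired with the realized upwind fluxes
            drain += info["upwind_sum"]
            if name == "p":
                # depolymerization release into the transported cells
                rel = (p_.v_depoly / p_.delta) * dt
                pos = v > 0
                state.g[pos, :-1] += rel * f[pos, :-1]
                state.g[~pos, 1:] += rel * f[~pos, 1:]
            nu = p_.delta * np.abs(v) / 2.0
            # content change of the stabilizing pass, evaluated on its input
            corr -= (nu / p_.delta) * (new[:, 0] - new[:, -1])
            new = stabilizing_diffusion(new, nu, dt, grid)
            setattr(state, name, new)
        mem.g_m -= (p_.v_poly * mem.g_m / p_.delta) * drain * dt
        state.g[:, 0] += corr * dt / dz
        if np.any(mem.g_m < 0):
            self._clamp(mem.g_m)

    # -- diffusion -----------------------------------------------------------
    def _diffusion(self, state: CytosolState, mem: MembraneState, dt: float):
        p_ = self.params
        for name, D in (("g", p_.D_g), ("arp", p_.D_arp), ("cor", p_.D_cor),
                        ("rac", p_.D_rac), ("rac_star", p_.D_rac)):
            setattr(state, name,
                    diffuse_cytosol(getattr(state, name), D, dt, self.grid,
                                    _cache=self._cache))
        Dm = p_.wasp_membrane_diffusion
        if Dm > 0.0:
            for name in ("W", "W_star", "WA", "WAG"):
                setattr(mem, name, _diffuse_membrane_1d(
                    getattr(mem, name), Dm, dt, self.grid, self._cache))

    # -- step ----------------------------------------------------------------
    def step(self, state: CytosolState, mem: MembraneState, t: float,
             dt: float | None = None):
        """Advance one time step (Strang-style reaction/transport split)."""
        dt = self.grid.dt if dt is None else dt
        total = sum(float(f.sum()) for _, f in state.items())
        if not np.isfinite(total):
            raise SolverError("non-finite density entering step")
        half = dt / 2.0
        self._bulk_reactions(state, half)
        self._membrane_phase(state, mem, t, half)
        self._transport(state, mem, dt)
        self._diffusion(state, mem, dt)
        self._bulk_reactions(state, half)
        self._membrane_phase(state, mem, t + half, half)
        self._postcheck(state, mem)
        return state, mem

    def _clamp(self, arr):
        neg = arr < 0
        if np.any(neg):
            lost = float(arr[neg].sum())
            if lost < -1e-6:
                raise SolverError(
                    f"density went negative beyond clamp tolerance ({lost:g})")
            self.clamped_mass += -lost
            self.n_clamp_events += int(neg.sum())
            arr[neg] = 0.0

    def _postcheck(self, state: CytosolState, mem: MembraneState):
        for _, a in list(state.items()) + list(mem.items()):
            if not np.all(np.isfinite(a)):
                raise SolverError("non-finite density encountered")
            if np.any(a < 0):
                self._clamp(a)


@dataclass
class Trajectory:
    """In-memory result of a run: snapshots at the output cadence."""

    config: SimulationConfig
    times: np.ndarray
    states: list
    membranes: list
    clamped_mass: float = 0.0

    def __len__(self):
        return len(self.times)


def run(config: SimulationConfig, progress=None) -> Trajectory:
    """Run a configuration to t_end, collecting snapshots at the cadence."""
    sim = Simulator(config)
    state, mem = sim.initial()
    dt = config.grid.dt
    n_steps = int(round(config.t_end / dt))
    every = max(1, int(round(config.output_every / dt)))
    times = [0.0]
    states = [state.copy()]
    membranes = [mem.copy()]
    t = 0.0
    for i in range(n_steps):
        state, mem = sim.step(state, mem, t, dt)
        t = (i + 1) * dt
        if (i + 1) % every == 0 or i == n_steps - 1:
            times.append(t)
            states.append(state.copy())
            membranes.append(mem.copy())
        if progress is not None:
            progress(i, n_steps)
    return Trajectory(config=config, times=np.asarray(times), states=states,
                      membranes=membranes, clamped_mass=sim.clamped_mass)
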