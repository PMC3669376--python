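"""Translate simulation fields into measured quantities.

Covers reconstruction of the F-actin concentration field from pointed-end
densities, TIRF-style shallow z-integrals, threshold-based wave-front
tracking, and the global conservation audit used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .params import GridSpec, ModelParams
from .state import CytosolState, MembraneState

__all__ = [
    "factin_field", "tirf_intensity", "track_fronts", "conservation_audit",
    "ObservableSeries", "FrontTrack", "observable_series",
]


def factin_field(state: CytosolState, grid: GridSpec, delta: float):
    """F-actin concentration F(x, z) reconstructed from pointed ends.

    A filament whose pointed end sits at height z' contributes one subunit
    at every height below z', so F(x,z) = (1/delta) * integral from z to Lz
    of the total pointed-end density.  F is non-increasing in z and vanishes
    at the top of the domain whenever no filament reaches it.
    """
    ptot = state.p + state.r + state.c
    rev = np.cumsum(ptot[:, ::-1], axis=1)[:, ::-1] * grid.dz
    return rev / delta


def tirf_intensity(field, depth: float, grid: GridSpec):
    """Shallow z-integral I(x) of a field over [0, depth] (uM*um).

    Emulates TIRF microscopy, which reports density within a thin slab above
    the substrate; ``depth`` need not be a multiple of dz (the partially
    covered cell contributes its overlapped fraction).  Linear in the field.
    """
    if not (0.0 < depth <= grid.Lz + 1e-12):
        raise ValueError(f"TIRF depth {depth} outside (0, Lz]")
    field = np.asarray(field)
    n_full = int(np.floor(depth / grid.dz + 1e-12))
    n_full = min(n_full, grid.nz)
    I = field[:, :n_full].sum(axis=1) * grid.dz
    frac = depth - n_full * grid.dz
    if frac > 1e-12 and n_full < grid.nz:
        I = I + field[:, n_full] * frac
    return I


@dataclass
class FrontTrack:
    """Threshold-crossing tracks of one wave front."""

    times: np.ndarray
    positions: np.ndarray      # outermost threshold crossing (um), NaN if absent
    speeds: np.ndarray         # centred differences of median-filtered positions
    peak_heights: np.ndarray
    half_widths: np.ndarray    # outer crossing to interval peak


def _crossings(x, I, thr):
    """Sub-cell interpolated crossing positions of I(x) = thr, and intervals."""
    above = I >= thr
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    # split into maximal runs
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    intervals = []
    for run in runs:
        i0, i1 = run[0], run[-1]
        if i0 > 0:
            f = (thr - I[i0 - 1]) / (I[i0] - I[i0 - 1])
            left = x[i0 - 1] + f * (x[i0] - x[i0 - 1])
        else:
            left = x[0]
        if i1 < len(x) - 1:
            f = (thr - I[i1]) / (I[i1 + 1] - I[i1])
            right = x[i1] + f * (x[i1 + 1] - x[i1])
        else:
            right = x[-1]
        ipk = run[np.argmax(I[run])]
        intervals.append((left, right, x[ipk], I[ipk]))
    return intervals


def _median3(a):
    out = a.copy()
    if len(a) >= 3:
        stack = np.vstack([a[:-2], a[1:-1], a[2:]])
        allnan = np.all(np.isnan(stack), axis=0)
        med = np.full(stack.shape[1], np.nan)
        if (~allnan).any():
            med[~allnan] = np.nanmedian(stack[:, ~allnan], axis=0)
        out[1:-1] = med
    return out


def track_fronts(times, I_series, grid: GridSpec, threshold_fraction=0.5):
    """Track outward wave fronts of a TIRF intensity series.

    The detection threshold at each time is ``threshold_fraction`` times the
    running (cumulative) peak intensity, so a decaying or annihilated wave
    drops below detection instead of tracking noise.  Returns a dict with
    left/right :class:`FrontTrack` objects (outermost crossings), the
    per-time detection threshold, and the raw above-threshold intervals.
    """
    times = np.asarray(times, dtype=float)
    I_series = np.asarray(I_series, dtype=float)
    if I_series.ndim != 2 or len(times) != I_series.shape[0]:
        raise ValueError("I_series must be (n_times, nx) matching times")
    x = grid.x_centers
    running_peak = np.maximum.accumulate(I_series.max(axis=1))
    thr = threshold_fraction * running_peak
    n = len(times)
    left = np.full(n, np.nan)
    right = np.full(n, np.nan)
    peak = np.full(n, np.nan)
    width_l = np.full(n, np.nan)
    width_r = np.full(n, np.nan)
    intervals_all = []
    for k in range(n):
        if running_peak[k] <= 0:
            intervals_all.append([])
            continue
        ivs = _crossings(x, I_series[k], thr[k])
        intervals_all.append(ivs)
        if not ivs:
            continue
        left[k] = min(iv[0] for iv in ivs)
        right[k] = max(iv[1] for iv in ivs)
        peak[k] = max(iv[3] for iv in ivs)
        lv = min(ivs, key=lambda iv: iv[0])
        rv = max(ivs, key=lambda iv: iv[1])
        width_l[k] = lv[2] - lv[0]
        width_r[k] = rv[1] - rv[2]

    def _speeds(pos):
        sm = _median3(pos)
        v = np.full(n, np.nan)
        if n >= 3:
            dtv = times[2:] - times[:-2]
            v[1:-1] = (sm[2:] - sm[:-2]) / dtv
        return v

    return {
        "left": FrontTrack(times, left, _speeds(left), peak, width_l),
        "right": FrontTrack(times, right, _speeds(right), peak, width_r),
        "threshold": thr,
        "intervals": intervals_all,
    }


def initiation_time(times, I_series, grid: GridSpec, x_probe: float,
                    level: float):
    """First time the intensity at ``x_probe`` exceeds ``level`` (else NaN).

    The wave-development metric: the time a developing wave needs to reach a
    probe position away from the nucleation site, judged against an absolute
    detection level (a running-peak threshold is undefined before any wave
    exists).
    """
    times = np.asarray(times, dtype=float)
    I_series = np.asarray(I_series, dtype=float)
    i = int(np.clip(round(x_probe / grid.dx - 0.5), 0, grid.nx - 1))
    hit = np.flatnonzero(I_series[:, i] >= level)
    return float(times[hit[0]]) if len(hit) else float("nan")


def conservation_audit(state: CytosolState, mem: MembraneState,
                       grid: GridSpec, params: ModelParams) -> dict:
    """Global totals of the four conserved budgets (uM*um^2 per unit y).

    Every pool containing each species is summed: the actin budget counts
    free G-actin (cytosolic and membrane-bound), the G-actin inside
    branching complexes, the length-1/2 membrane filaments, and the
    z-weighted subunit content of the continuum filament fields; the
    pseudo-steady length-3 pool is a flux conduit and holds no audited mass
    (its content, ~3 filament-equivalents, is exchanged instantaneously by
    construction).  Arp2/3 counts free, complex-bound and cap-bound forms;
    coronin counts free and cap-bound; Rac counts both activity states.
    """
    dV = grid.dx * grid.dz
    dx = grid.dx
    z = grid.z_centers[None, :]
    ptot = state.p + state.r + state.c
    actin = (state.g.sum() * dV
             + (mem.g_m + mem.WAG).sum() * dx
             + (mem.s_p1 + mem.s_r1 + mem.s_c1).sum() * dx
             + 2.0 * (mem.s_p2 + mem.s_r2 + mem.s_c2).sum() * dx
             + (z * ptot).sum() * dV / params.delta)
    arp = (state.arp.sum() * dV + state.r.sum() * dV
           + (mem.WA + mem.WAG + mem.s_r1 + mem.s_r2).sum() * dx)
    cor = (state.cor.sum() * dV + state.c.sum() * dV
           + (mem.s_c1 + mem.s_c2).sum() * dx)
    rac = (state.rac + state.rac_star).sum() * dV
    wasp = mem.wasp_total().sum() * dx
    return {"actin": float(actin), "arp": float(arp), "cor": float(cor),
            "rac": float(rac), "wasp": float(wasp)}


@dataclass
class ObservableSeries:
    """Per-snapshot observables of a trajectory.

    TIRF traces are stored per species key; the budget audit is one row per
    time.  ``to_frame`` flattens everything into a tidy DataFrame for CSV
    export (one row per time, documented column order).
    """

    times: np.ndarray
    tirf: dict = dfield(default_factory=dict)   # name -> (n_times, nx)
    audit: pd.DataFrame | None = None
    zscan: np.ndarray | None = None             # F(x, z) of the last snapshot

    def __post_init__(self):
        t = np.asarray(self.times)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for name, tr in sorted(self.tirf.items()):
            cols[f"{name}_peak"] = tr.max(axis=1)
            cols[f"{name}_total"] = tr.sum(axis=1)
        df = pd.DataFrame(cols)
        if self.audit is not None:
            df = df.join(self.audit.reset_index(drop=True))
        return df


def observable_series(traj, species=("factin", "arp", "cor_caps", "rac_star",
                                     "arp_free", "g")) -> ObservableSeries:
    """Standard observable extraction from a :class:`Trajectory`.

    TIRF traces use the configured depth.  ``factin`` integrates the
    reconstructed F-actin field; ``arp`` integrates total Arp2/3 near the
    surface (caps + complexes reconstructed as cap density + free);
    ``cor_caps`` is the coronin-capped pointed-end density; ``arp_free`` and
    ``g`` are the free cytosolic species; ``rac_star`` is activated Rac.
    """
    grid = traj.config.grid
    params = traj.config.params
    depth = traj.config.tirf_depth
    nT = len(traj.times)
    out = {name: np.zeros((nT, grid.nx)) for name in species}
    audit_rows = []
    for k, (st, mm) in enumerate(zip(traj.states, traj.membranes)):
        F = factin_field(st, grid, params.delta)
        for name in species:
            if name == "factin":
                fld = F
            elif name == "arp":
                fld = st.r + st.arp
            elif name == "cor_caps":
                fld = st.c
            elif name == "arp_free":
                fld = st.arp
            elif name == "rac_star":
                fld = st.rac_star
            elif name == "g":
                fld = st.g
            else:
                fld = getattr(st, name)
            out[name][k] = tirf_intensity(fld, depth, grid)
        audit_rows.append(conservation_audit(st, mm, grid, params))
    audit = pd.DataFrame(audit_rows)
    zscan = factin_field(traj.states[-1], grid, params.delta)
    return ObservableSeries(times=np.asarray(traj.times), tirf=out,
                            audit=audit, zscan=zscan)
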