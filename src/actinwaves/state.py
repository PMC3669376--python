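"""State containers for the continuum model.

Cytosolic fields live on the (nx, nz) cell-centred grid; membrane fields are
per-x arrays of length nx.  Arrays are indexed ``field[i_x, j_z]`` with
``j_z = 0`` the cell adjacent to the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .params import GridSpec, ModelParams

CYTOSOL_FIELDS = ("p", "r", "c", "g", "arp", "cor", "rac", "rac_star")
MEMBRANE_FIELDS = ("g_m", "W", "W_star", "WA", "WAG",
                   "s_p1", "s_p2", "s_r1", "s_r2", "s_c1", "s_c2")


@dataclass
class CytosolState:
    """Pointed-end densities (p, r, c) and diffusible concentrations, in uM.

    p: free pointed ends; r: Arp2/3-capped; c: coronin-capped.
    g, arp, cor: free G-actin, Arp2/3, coronin; rac / rac_star: inactive and
    activated Rac.
    """

    p: np.ndarray
    r: np.ndarray
    c: np.ndarray
    g: np.ndarray
    arp: np.ndarray
    cor: np.ndarray
    rac: np.ndarray
    rac_star: np.ndarray

    @classmethod
    def zeros(cls, grid: GridSpec) -> "CytosolState":
        return cls(*(np.zeros((grid.nx, grid.nz)) for _ in CYTOSOL_FIELDS))

    def copy(self) -> "CytosolState":
        return CytosolState(*(getattr(self, n).copy() for n in CYTOSOL_FIELDS))

    def check(self) -> None:
        shape = self.p.shape
        for n in CYTOSOL_FIELDS:
            a = getattr(self, n)
            if a.shape != shape:
                raise ValueError(f"field {n} has shape {a.shape}, expected {shape}")
            if not np.all(np.isfinite(a)):
                raise FloatingPointError(f"non-finite values in field {n}")

    def items(self):
        for n in CYTOSOL_FIELDS:
            yield n, getattr(self, n)


@dataclass
class MembraneState:
    """Per-x membrane surface densities (uM*um); none of these diffuse.

    g_m: membrane-bound G-actin.  W, W_star, WA, WAG: the WASP cycle
    (inactive, activated, WASP-Arp2/3, and the full branching complex with
    G-actin).  s_t1 / s_t2: filaments of length 1 and 2 of pointed-end type
    t in {p, r, c}, whose dynamics differ from the continuum fields.
    """

    g_m: np.ndarray
    W: np.ndarray
    W_star: np.ndarray
    WA: np.ndarray
    WAG: np.ndarray
    s_p1: np.ndarray
    s_p2: np.ndarray
    s_r1: np.ndarray
    s_r2: np.ndarray
    s_c1: np.ndarray
    s_c2: np.ndarray

    @classmethod
    def resting(cls, grid: GridSpec, params: ModelParams) -> "MembraneState":
        """All WASP inactive, no membrane G-actin, empty filament pools."""
        m = cls(*(np.zeros(grid.nx) for _ in MEMBRANE_FIELDS))
        m.W[:] = params.W_total
        return m

    def copy(self) -> "MembraneState":
        return MembraneState(*(getattr(self, n).copy() for n in MEMBRANE_FIELDS))

    def wasp_total(self) -> np.ndarray:
        return self.W + self.W_star + self.WA + self.WAG

    def check(self, params: ModelParams | None = None, tol: float = 1e-8) -> None:
        n0 = self.g_m.shape
        for n in MEMBRANE_FIELDS:
            a = getattr(self, n)
            if a.shape != n0:
                raise ValueError(f"membrane field {n} has shape {a.shape}")
            if not np.all(np.isfinite(a)):
                raise FloatingPointError(f"non-finite values in membrane field {n}")
        if params is not None:
            drift = np.max(np.abs(self.wasp_total() - params.W_total))
            if drift > tol * max(params.W_total, 1.0):
                raise FloatingPointError(
                    f"local WASP conservation violated (max drift {drift:g})")

    def items(self):
        for n in MEMBRANE_FIELDS:
            yield n, getattr(self, n)


@dataclass
class BarbedEndDensity:
    """Total barbed-end surface density B(x) in uM*um.

    Derived quantity: the column integral of (p + r + c) plus the length-1/2
    membrane pools plus the pseudo-steady length-3 amount.  Barbed ends of
    every filament sit at the membrane, so B is a per-x surface density.
    """

    B: np.ndarray


def initial_state(grid: GridSpec, params: ModelParams) -> tuple[CytosolState, MembraneState]:
    """Well-mixed rest state: all protein free and uniform, no filaments."""
    s = CytosolState.zeros(grid)
    s.g[:] = params.A_total
    s.arp[:] = params.Arp_total
    s.cor[:] = params.Cor_total
    s.rac[:] = params.Rac_total
    m = MembraneState.resting(grid, params)
    return s, m
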