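"""Model parameters and grid geometry.

Unit conventions used throughout the package:

* length in micrometres (um), time in seconds (s);
* cytosolic concentrations in micromolar (uM);
* membrane surface densities in uM*um, i.e. the unit a cytosolic
  concentration acquires when integrated over a vertical slab.  This choice
  makes every membrane/cytosol exchange flux (uM*um/s) directly usable as a
  boundary flux of a cytosolic field without conversion factors.

With these conventions second-order rate constants involving one surface
density carry units of (uM*um)^-1 s^-1, those between two cytosolic species
uM^-1 s^-1, and the membrane-attachment constant ``k_gm_on`` is a
permeability (um/s).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


@dataclass
class ModelParams:
    """Rate constants, totals and diffusivities of the actin-wave model.

    Defaults reproduce the packaged base parameter set: protein totals and
    diffusivities sit in physiological ranges, while kinetic constants were
    chosen so that the resting state is sub-excitable and a localized
    nucleation transient ignites a travelling wave (see docs/methods.md for
    the scale analysis behind each value).
    """

    #: length of one F-actin subunit (um); half the length of a G-actin monomer
    delta: float = 0.0027

    # --- totals -------------------------------------------------------------
    A_total: float = 50.0      #: total actin (uM)
    Arp_total: float = 0.8     #: total Arp2/3 (uM)
    Cor_total: float = 2.0     #: total coronin (uM)
    Rac_total: float = 2.0     #: total Rac (uM)
    W_total: float = 0.6       #: total WASP surface density (uM*um)

    # --- diffusivities (um^2/s) ----------------------------------------------
    D_g: float = 5.0
    D_arp: float = 2.5
    D_cor: float = 2.5
    D_rac: float = 1.5

    # --- filament kinetics ----------------------------------------------------
    k_dim: float = 2.0e-5      #: dimerization, (uM*um)^-1 s^-1
    k_debranch: float = 0.35   #: branch detachment from coronin-capped ends, s^-1
    k_cor: float = 0.15        #: coronin binding to Arp2/3-capped ends, uM^-1 s^-1
    v_poly: float = 0.10       #: polymerization speed constant, um/s per (uM*um) of g_m
    v_depoly: float = 0.35     #: depolymerization speed at free pointed ends, um/s
    #: membrane polymerization rate constant, (uM*um)^-1 s^-1; default v_poly/delta
    k_poly: float | None = None
    #: depolymerization rate constant, s^-1; default v_depoly/delta
    k_depoly: float | None = None

    # --- signalling layer ------------------------------------------------------
    k_rac_act: float = 12.0     #: Rac activation by barbed ends, (uM*um)^-1 um/s
    k_rac_deact: float = 0.6   #: spontaneous Rac deactivation, s^-1
    k_rac_spont: float = 0.001  #: spontaneous cytosolic Rac activation, s^-1
    k_wasp_act: float = 1.0    #: WASP activation by activated Rac, uM^-1 s^-1
    k_wasp_deact: float = 1.0  #: spontaneous WASP deactivation, s^-1
    k_arp_on: float = 1.0      #: Arp2/3 binding to activated WASP, uM^-1 s^-1
    k_arp_off: float = 1.0     #: spontaneous Arp2/3 unbinding, s^-1
    k_gact_on: float = 0.3    #: G-actin binding to WASP-Arp2/3, (uM*um)^-1 s^-1
    k_gact_off: float = 1.0    #: spontaneous G-actin unbinding, s^-1
    k_branch: float = 6.0      #: branching by the WAG complex, (uM*um)^-1 s^-1
    k_gm_on: float = 0.08      #: membrane binding of G-actin, um/s
    k_gm_off: float = 1.5      #: membrane detachment of G-actin, s^-1

    #: diffusivity of WASP-cycle species on the membrane (um^2/s); 0 = immobile
    wasp_membrane_diffusion: float = 0.0

    # --- structural variant switches ------------------------------------------
    #: after branching the WASP molecule returns to the activated state W*;
    #: set False to return it to the inactive pool W instead
    branch_returns_wasp_active: bool = True
    #: spontaneous debranching rate acting directly on Arp2/3-capped filaments
    #: (s^-1); used by the coronin-free variant, 0 in the base model
    k_debranch_r: float = 0.0
    #: coronin binding on the length<=2 membrane pools (same k_cor); disabling
    #: makes s_c1/s_c2 unreachable, as for the length-3 pool
    short_pool_coronin: bool = True
    #: if True the PTEN surrogate also zeroes spontaneous Rac activation in the
    #: bulk above the region; default zeroes only the barbed-end-driven flux
    pten_blocks_spont: bool = False

    def __post_init__(self) -> None:
        if self.k_poly is None:
            self.k_poly = self.v_poly / self.delta
        if self.k_depoly is None:
            self.k_depoly = self.v_depoly / self.delta
        self.validate()

    def validate(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if not self.W_total > 0:
            raise ValueError("W_total must be positive")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool) or v is None:
                continue
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite")
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v!r}")

    # --- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GridSpec:
    """Cell-centred finite-volume grid on the (x, z) cross-section.

    x in [0, Lx] runs along the substrate-attached membrane, z in [0, Lz] is
    the vertical direction of filament growth; the membrane sits at z = 0.
    Cell i in x covers [i*dx, (i+1)*dx); likewise in z.
    """

    Lx: float = 20.0
    Lz: float = 3.0
    nx: int = 128
    nz: int = 48
    dt: float = 0.025

    def __post_init__(self) -> None:
        if self.Lx <= 0 or self.Lz <= 0:
            raise ValueError("domain extents must be positive")
        if self.nx < 1 or self.nz < 2:
            raise ValueError("need nx >= 1 and nz >= 2 cells")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def dx(self) -> float:
        return self.Lx / self.nx

    @property
    def dz(self) -> float:
        return self.Lz / self.nz

    @property
    def x_centers(self):
        import numpy as np

        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def z_centers(self):
        import numpy as np

        return (np.arange(self.nz) + 0.5) * self.dz

    def to_dict(self) -> dict:
        return {"Lx": self.Lx, "Lz": self.Lz, "nx": self.nx, "nz": self.nz,
                "dt": self.dt}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        known = {"Lx", "Lz", "nx", "nz", "dt"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown GridSpec keys: {sorted(unknown)}")
        return cls(**d)
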