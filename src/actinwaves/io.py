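"""Configuration files, canned scenarios, and trajectory containers.

Configuration format is YAML (one documented dialect; see the key reference
in the README).  Trajectories are stored in a single HDF5 file per run with
a verbatim config snapshot, making containers self-describing; observables
export to CSV for eyeball diffing.
"""

from __future__ import annotations

import io as _io
import os

import h5py
import numpy as np
import yaml

from .engine import (PTENRegion, SimulationConfig, StimulusProtocol,
                     Trajectory)
from .params import GridSpec, ModelParams
from .state import (CYTOSOL_FIELDS, MEMBRANE_FIELDS, CytosolState,
                    MembraneState)

SCHEMA_VERSION = 1

__all__ = ["load_config", "save_config", "scenario", "SCENARIOS",
           "write_container", "read_container", "ContainerError",
           "SCHEMA_VERSION"]


class ContainerError(RuntimeError):
    """Corrupt, truncated, or incompatible trajectory container."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def load_config(path) -> SimulationConfig:
    """Load and fully validate a YAML configuration.

    An empty file yields the packaged default configuration; unknown keys
    are rejected with the offending name.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(doc)}")
    return SimulationConfig.from_dict(doc)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# canned scenarios
# --------------------------------------------------------------------------

def _base(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(params=ModelParams(), grid=GridSpec())
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _single_precursor() -> SimulationConfig:
    cfg = _base(label="single_precursor", t_end=150.0)
    Lx = cfg.grid.Lx
    cfg.stimuli = [StimulusProtocol(x0=Lx / 2 - 1.0, x1=Lx / 2 + 1.0,
                                    start=5.0, duration=20.0, fold=400.0)]
    return cfg


def _collision() -> SimulationConfig:
    cfg = _base(label="collision", t_end=170.0)
    Lx = cfg.grid.Lx
    for x0 in (Lx / 2 - 6.0, Lx / 2 + 4.0):
        cfg.stimuli.append(StimulusProtocol(x0=x0, x1=x0 + 2.0, start=5.0,
                                            duration=20.0, fold=400.0))
    return cfg


def _feedback_off() -> SimulationConfig:
    cfg = _single_precursor()
    cfg.label = "feedback_off"
    cfg.params = cfg.params.replace(k_rac_act=0.0)
    return cfg


def _coronin_off() -> SimulationConfig:
    # no coronin: spontaneous debranching compensates filament deconstruction
    cfg = _single_precursor()
    cfg.label = "coronin_off"
    cfg.params = cfg.params.replace(k_cor=0.0, Cor_total=0.0,
                                    k_debranch_r=cfg.params.k_debranch)
    return cfg


def _coronin_off_low_debranch() -> SimulationConfig:
    # reduced effective debranching: altered structure, no travelling back
    cfg = _coronin_off()
    cfg.label = "coronin_off_low_debranch"
    cfg.params = cfg.params.replace(
        k_debranch_r=cfg.params.k_debranch / 4.0)
    return cfg


def _pten_block() -> SimulationConfig:
    cfg = _base(label="pten_block", t_end=200.0)
    Lx = cfg.grid.Lx
    cfg.stimuli = [StimulusProtocol(x0=Lx / 2 - 3.0, x1=Lx / 2 - 1.0,
                                    start=5.0, duration=20.0, fold=400.0)]
    cfg.pten_regions = [PTENRegion(x0=Lx / 2 + 4.0, x1=Lx, onset=0.0)]
    return cfg


def _pten_moving() -> SimulationConfig:
    # waves on both sides of a finite PTEN block; once the block translates,
    # the front on its leading side is pushed back while the front on the
    # trailing side advances into the vacated membrane
    cfg = _base(label="pten_moving", t_end=280.0)
    Lx = cfg.grid.Lx
    cfg.stimuli = [
        StimulusProtocol(x0=3.5, x1=5.5, start=5.0, duration=20.0, fold=400.0),
        StimulusProtocol(x0=Lx - 5.5, x1=Lx - 3.5, start=5.0, duration=20.0,
                         fold=400.0),
    ]
    cfg.pten_regions = [PTENRegion(x0=Lx / 2 - 2.5, x1=Lx / 2 + 2.5,
                                   onset=0.0, speed=-0.05, move_start=120.0)]
    return cfg


def _pten_split() -> SimulationConfig:
    # intrusion wider than the activated-Rac decay length, so the covered
    # strip is out of reach of laterally diffusing Rac activity
    cfg = _single_precursor()
    cfg.label = "pten_split"
    cfg.t_end = 260.0
    Lx = cfg.grid.Lx
    cfg.pten_regions = [PTENRegion(x0=Lx / 2 - 3.0, x1=Lx / 2 + 3.0,
                                   onset=100.0)]
    return cfg


def _high_arp_membrane_diffusion() -> SimulationConfig:
    cfg = _single_precursor()
    cfg.label = "high_arp_membrane_diffusion"
    cfg.params = cfg.params.replace(
        Arp_total=5.0 * cfg.params.Arp_total,
        k_branch=cfg.params.k_branch / 5.0,
        k_arp_on=cfg.params.k_arp_on / 2.0,
        wasp_membrane_diffusion=0.1)
    return cfg


SCENARIOS = {
    "single_precursor": _single_precursor,
    "collision": _collision,
    "feedback_off": _feedback_off,
    "coronin_off": _coronin_off,
    "coronin_off_low_debranch": _coronin_off_low_debranch,
    "pten_block": _pten_block,
    "pten_moving": _pten_moving,
    "pten_split": _pten_split,
    "high_arp_membrane_diffusion": _high_arp_membrane_diffusion,
}


def scenario(name: str) -> SimulationConfig:
    """Deterministic desk-scale configuration for a named scenario."""
    try:
        factory = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    cfg = factory()
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# trajectory container
# --------------------------------------------------------------------------

def write_container(traj: Trajectory, path) -> None:
    """Write a trajectory to one self-describing HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        buf = _io.StringIO()
        yaml.safe_dump(traj.config.to_dict(), buf, sort_keys=False)
        f.attrs["config_yaml"] = buf.getvalue()
        f.attrs["clamped_mass"] = traj.clamped_mass
        f.create_dataset("times", data=np.asarray(traj.times))
        grp = f.create_group("fields")
        for name in CYTOSOL_FIELDS:
            data = np.stack([getattr(s, name) for s in traj.states])
            grp.create_dataset(name, data=data, compression="gzip",
                               compression_opts=4)
        grp = f.create_group("membrane")
        for name in MEMBRANE_FIELDS:
            data = np.stack([getattr(m, name) for m in traj.membranes])
            grp.create_dataset(name, data=data, compression="gzip",
                               compression_opts=4)


def read_container(path) -> Trajectory:
    """Re-load a trajectory; raises :class:`ContainerError` on any defect."""
    if not os.path.exists(path):
        raise ContainerError(f"no such container: {path}")
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("schema_version", -1))
            if version > SCHEMA_VERSION:
                raise ContainerError(
                    f"container schema v{version} is newer than supported "
                    f"v{SCHEMA_VERSION}")
            if version < 0:
                raise ContainerError("missing schema version attribute")
            config = SimulationConfig.from_dict(
                yaml.safe_load(f.attrs["config_yaml"]))
            times = f["times"][...]
            states = []
            membranes = []
            for k in range(len(times)):
                states.append(CytosolState(
                    *(f["fields"][n][k] for n in CYTOSOL_FIELDS)))
                membranes.append(MembraneState(
                    *(f["membrane"][n][k] for n in MEMBRANE_FIELDS)))
            clamped = float(f.attrs.get("clamped_mass", 0.0))
    except ContainerError:
        raise
    except (OSError, KeyError) as e:
        raise ContainerError(f"corrupt or truncated container {path}: {e}")
    return Trajectory(config=config, times=times, states=states,
                      membranes=membranes, clamped_mass=clamped)
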