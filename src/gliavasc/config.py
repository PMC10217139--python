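"""YAML run configuration: one file drives an end-to-end experiment.

The config declares the synthetic conditions (or input files), channel
roles, every pipeline parameter (defaulting to the published values), and
the statistical design.  CLI flags mirror config keys and override them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .aqp4 import SurfaceParams
from .contact import ContactParams
from .core_io import TWO_PHOTON_VOXEL, VoxelSize
from .soma import SomaParams
from .synthetic import SynthParams
from .thresholding import METHOD_NAMES


class ConfigError(ValueError):
    """A config file failed validation."""


def _build(cls, mapping: dict[str, Any], errors: list[str], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        errors.append(f"{section}: unknown keys {sorted(unknown)}")
        mapping = {k: v for k, v in mapping.items() if k in known}
    for key in ("opening_radii", "shape", "soma_volume_range_um3",
                "process_length_um"):
        if key in mapping and isinstance(mapping[key], list):
            mapping[key] = tuple(mapping[key])
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


@dataclasses.dataclass
class RunConfig:
    voxel: VoxelSize = TWO_PHOTON_VOXEL
    soma: SomaParams = dataclasses.field(default_factory=SomaParams)
    contact: ContactParams = dataclasses.field(default_factory=ContactParams)
    surface: SurfaceParams = dataclasses.field(default_factory=SurfaceParams)
    synth: SynthParams = dataclasses.field(default_factory=SynthParams)
    channel_roles: dict[int, str] = dataclasses.field(
        default_factory=lambda: {0: "glia", 1: "vessel"}
    )
    conditions: tuple[str, ...] = ("control",)
    baseline: str = "control"
    paired: bool = True
    subjects_per_condition: int = 5
    stages: tuple[str, ...] = ()
    seed: int = 0


def validate_config(data: dict[str, Any]) -> tuple[RunConfig | None, list[str]]:
    """Validate a parsed config mapping; returns (config, error list)."""
    errors: list[str] = []
    data = dict(data or {})

    voxel = TWO_PHOTON_VOXEL
    if "voxel" in data:
        try:
            d = data["voxel"]
            voxel = VoxelSize(float(d["dx"]), float(d["dy"]), float(d["dz"]))
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"voxel: {exc}")

    soma = _build(SomaParams, data.get("soma", {}), errors, "soma")
    contact = _build(ContactParams, data.get("contact", {}), errors, "contact")
    surface = _build(SurfaceParams, data.get("surface", {}), errors, "surface")
    synth_map = dict(data.get("synth", {}))
    if "voxel" not in synth_map:
        synth_map["voxel"] = voxel
    synth = _build(SynthParams, synth_map, errors, "synth")

    for section, params, field in (
        ("soma", soma, "threshold_method"),
        ("contact", contact, "threshold_method"),
        ("surface", surface, "vessel_threshold_method"),
        ("surface", surface, "aqp4_threshold_method"),
    ):
        if params is not None and getattr(params, field) not in METHOD_NAMES:
            errors.append(f"{section}.{field}: unknown method")

    roles = {0: "glia", 1: "vessel"}
    if "channel_roles" in data:
        try:
            roles = {int(k): str(v) for k, v in data["channel_roles"].items()}
        except (TypeError, ValueError) as exc:
            errors.append(f"channel_roles: {exc}")
        for idx, role in roles.items():
            if idx < 0:
                errors.append(f"channel_roles: negative channel index {idx}")
            if role not in ("glia", "vessel", "aqp4", "nuclei"):
                errors.append(f"channel_roles: unknown role {role!r}")

    conditions = tuple(data.get("conditions", ("control",)))
    baseline = data.get("baseline", conditions[0] if conditions else "control")
    if baseline not in conditions:
        errors.append(f"baseline {baseline!r} not among conditions {conditions}")
    stages = tuple(data.get("stages", ()))
    for s in stages:
        if s not in ("simulate", "soma", "contact", "aqp4", "area2d", "report"):
            errors.append(f"unknown stage {s!r}")
    n_subj = int(data.get("subjects_per_condition", 5))
    if n_subj < 1:
        errors.append("subjects_per_condition must be >= 1")

    if errors or soma is None or contact is None or surface is None or synth is None:
        return None, errors
    return (
        RunConfig(
            voxel=voxel,
            soma=soma,
            contact=contact,
            surface=surface,
            synth=synth,
            channel_roles=roles,
            conditions=conditions,
            baseline=baseline,
            paired=bool(data.get("paired", True)),
            subjects_per_condition=n_subj,
            stages=stages,
            seed=int(data.get("seed", 0)),
        ),
        [],
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; raises ConfigError on any problem."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg, errors = validate_config(data)
    if cfg is None:
        raise ConfigError("; ".join(errors))
    return cfg
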