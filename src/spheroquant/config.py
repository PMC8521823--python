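"""Pipeline configuration: the package's analogue of a saved analysis pipeline.

A :class:`PipelineConfig` names the input images, maps channel roles
(nuclei stain, pimonidazole, DRAQ7, mAG, mKO2, PBMC) to files or stack
planes, carries every segmentation/classification parameter, and toggles
the four analyses.  Configurations are YAML on disk, versioned, and
validated into a *list of violations* rather than a first-failure
exception, so a user sees everything wrong at once.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from .errors import ParameterError
from .segmentation import PrimaryParams, SecondaryParams

__all__ = [
    "SpheroidDetectionParams",
    "PositivityParams",
    "PipelineConfig",
    "validate_config",
    "load_config",
    "save_config",
    "ANALYSIS_ROLES",
]

#: channel roles each analysis needs mapped before it can run
ANALYSIS_ROLES = {
    "hypoxia": ("pimonidazole",),
    "death": ("DRAQ7",),
    "infiltration": ("PBMC",),
    "fucci": ("mAG", "mKO2"),
}

KNOWN_ROLES = ("DAPI", "pimonidazole", "DRAQ7", "mAG", "mKO2", "PBMC")


@dataclass
class SpheroidDetectionParams:
    """Whole-spheroid detection settings.

    ``source`` lists the channel roles merged into the detection image;
    empty means "use the nuclei source".  Manual thresholding is the
    preferred strategy for this task.
    """

    diameter_estimate_px: float = 600.0
    threshold_strategy: Literal["automatic", "manual"] = "manual"
    manual_threshold: float | None = None
    source: list[str] = field(default_factory=list)


@dataclass
class PositivityParams:
    """How per-object stain positivity is called for one channel."""

    strategy: Literal["automatic", "manual"] = "automatic"
    manual_threshold: float | None = None


def _default_nuclei_params() -> PrimaryParams:
    return PrimaryParams(diameter_min_px=5.0, diameter_max_px=20.0)


def _default_pbmc_params() -> PrimaryParams:
    return PrimaryParams(diameter_min_px=4.0, diameter_max_px=16.0)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, defaults materialisable.

    Input is either a multi-plane TIFF stack (``stack_path`` +
    ``stack_roles`` mapping role -> plane index) or per-channel files
    (``channel_files`` mapping role -> path).  ``nuclei_source`` lists the
    roles whose per-pixel maximum forms the nuclear image (one role = use
    it directly).
    """

    version: int = 1
    stack_path: str | None = None
    stack_roles: dict[str, int] = field(default_factory=dict)
    channel_files: dict[str, str] = field(default_factory=dict)
    pixel_size_um: float | None = None
    nuclei_source: list[str] = field(default_factory=lambda: ["DAPI"])
    nuclei_params: PrimaryParams = field(default_factory=_default_nuclei_params)
    pbmc_params: PrimaryParams = field(default_factory=_default_pbmc_params)
    secondary_params: SecondaryParams = field(default_factory=SecondaryParams)
    spheroid: SpheroidDetectionParams = field(
        default_factory=SpheroidDetectionParams
    )
    positivity: dict[str, PositivityParams] = field(default_factory=dict)
    bin_width_um: float = 25.0
    normalize: Literal["none", "ring_area"] = "none"
    analyses: dict[str, bool] = field(
        default_factory=lambda: {
            "hypoxia": False,
            "death": False,
            "infiltration": False,
            "fucci": False,
        }
    )
    out_dir: str = "spheroquant_out"
    seed: int = 0

    @property
    def mapped_roles(self) -> set[str]:
        return set(self.stack_roles) | set(self.channel_files)

    def enabled_analyses(self) -> list[str]:
        return [k for k, v in self.analyses.items() if v]

    def positivity_for(self, role: str) -> PositivityParams:
        return self.positivity.get(role, PositivityParams())


def validate_config(config: PipelineConfig) -> list[str]:
    """All invariant violations, as human-readable strings (empty = valid).

    Never mutates the config and never raises: violations are data.
    """
    v: list[str] = []
    has_stack = config.stack_path is not None
    has_files = bool(config.channel_files)
    if not has_stack and not has_files:
        v.append("no input: set stack_path or channel_files")
    if has_stack and has_files:
        v.append("ambiguous input: set stack_path or channel_files, not both")
    if has_stack and not config.stack_roles:
        v.append("stack_path set but stack_roles is empty")
    for role in config.mapped_roles:
        if role not in KNOWN_ROLES:
            v.append(f"unknown channel role {role!r}")
    for name, enabled in config.analyses.items():
        if name not in ANALYSIS_ROLES:
            v.append(f"unknown analysis {name!r}")
            continue
        if enabled:
            for role in ANALYSIS_ROLES[name]:
                if role not in config.mapped_roles:
                    v.append(
                        f"analysis '{name}' enabled but channel role "
                        f"'{role}' is not mapped"
                    )
    if not config.nuclei_source:
        v.append("nuclei_source is empty")
    for role in config.nuclei_source:
        if role not in config.mapped_roles:
            v.append(f"nuclei_source role '{role}' is not mapped")
    for role in config.spheroid.source:
        if role not in config.mapped_roles:
            v.append(f"spheroid source role '{role}' is not mapped")
    if not (config.bin_width_um > 0):
        v.append(f"bin_width_um must be > 0, got {config.bin_width_um}")
    if config.normalize not in ("none", "ring_area"):
        v.append(f"unknown normalize mode {config.normalize!r}")
    if config.pixel_size_um is not None and not (config.pixel_size_um > 0):
        v.append("pixel_size_um override must be > 0")
    for label, params in (
        ("nuclei_params", config.nuclei_params),
        ("pbmc_params", config.pbmc_params),
        ("secondary_params", config.secondary_params),
    ):
        try:
            params.validate()
        except ParameterError as exc:
            v.append(f"{label}: {exc}")
    if not (config.spheroid.diameter_estimate_px > 0):
        v.append("spheroid.diameter_estimate_px must be > 0")
    if (
        config.spheroid.threshold_strategy == "manual"
        and config.spheroid.manual_threshold is None
    ):
        v.append("spheroid manual threshold strategy needs manual_threshold")
    for role, pos in config.positivity.items():
        if pos.strategy == "manual" and pos.manual_threshold is None:
            v.append(f"positivity for '{role}': manual strategy needs a threshold")
        if pos.strategy not in ("automatic", "manual"):
            v.append(f"positivity for '{role}': unknown strategy {pos.strategy!r}")
    return v


# ---------------------------------------------------------------------------
# YAML round trip

def config_to_dict(config: PipelineConfig) -> dict:
    """Plain-dict form with every default materialised (YAML-safe)."""
    return asdict(config)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    for key, cls in (
        ("nuclei_params", PrimaryParams),
        ("pbmc_params", PrimaryParams),
        ("secondary_params", SecondaryParams),
        ("spheroid", SpheroidDetectionParams),
    ):
        if key in data and isinstance(data[key], dict):
            data[key] = cls(**data[key])
    if "positivity" in data:
        data["positivity"] = {
            role: (
                PositivityParams(**p) if isinstance(p, dict) else p
            )
            for role, p in data["positivity"].items()
        }
    return PipelineConfig(**data)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    return path
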