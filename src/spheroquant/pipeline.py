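"""Config-driven end-to-end execution of the spheroid analysis.

``run_pipeline`` sequences the whole workflow: load channels -> build the
nuclear image (optionally a per-pixel-max merge of several stains) ->
identify nuclei -> detect the spheroid footprint -> relate every object to
the surface -> measure intensities and call positives -> build the enabled
depth profiles -> write all artefacts.  One structured log line per stage
records object counts and computed thresholds; a resolved-config snapshot
(all defaults materialised, seed included) makes the run exactly
repeatable.  A stage failure aborts with the stage name and removes
partial outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import image_io, profiles, segmentation, spatial
from .config import (
    ANALYSIS_ROLES,
    PipelineConfig,
    save_config,
    validate_config,
)
from .errors import ConfigError, PipelineStageError, SpheroquantError
from .image_io import ChannelImage
from .profiles import DepthProfile
from .segmentation import LabelMap, SpheroidMask

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("spheroquant.pipeline")


@dataclass
class PipelineResult:
    """In-memory results plus the paths of every written artefact."""

    out_dir: Path
    nuclei: LabelMap
    spheroid: SpheroidMask
    nuclei_records: pd.DataFrame
    cells: LabelMap | None = None
    cell_records: pd.DataFrame | None = None
    pbmc: LabelMap | None = None
    pbmc_records: pd.DataFrame | None = None
    depth_profiles: dict[str, DepthProfile] = field(default_factory=dict)
    written: list[Path] = field(default_factory=list)


def _load_channels(config: PipelineConfig) -> dict[str, ChannelImage]:
    channels: dict[str, ChannelImage] = {}
    if config.stack_path is not None:
        stack = image_io.read_stack(
            config.stack_path, pixel_size_um=config.pixel_size_um
        )
        for role, plane in config.stack_roles.items():
            src = stack[int(plane)]
            channels[role] = ChannelImage(
                role, src.pixels, src.pixel_size_um
            )
    else:
        for role, path in config.channel_files.items():
            stack = image_io.read_stack(
                path, pixel_size_um=config.pixel_size_um
            )
            src = stack[0]
            channels[role] = ChannelImage(role, src.pixels, src.pixel_size_um)
    return channels


def _source_image(
    channels: dict[str, ChannelImage], roles: list[str]
) -> ChannelImage:
    if len(roles) == 1:
        return channels[roles[0]]
    return image_io.merge_channels([channels[r] for r in roles])


def _measure_and_flag(
    config: PipelineConfig,
    objects: LabelMap,
    channel: ChannelImage,
    records: pd.DataFrame,
    role: str,
) -> pd.DataFrame:
    """Attach {role}_mean/median/integrated and {role}_positive columns."""
    feats = profiles.measure_object_intensity(objects, channel)
    feats = feats.rename(
        columns={
            "mean": f"{role}_mean",
            "median": f"{role}_median",
            "integrated": f"{role}_integrated",
        }
    )
    records = records.merge(feats, on="object_id", how="left")
    pos = config.positivity_for(role)
    flags, thr = profiles.classify_positive(
        records[f"{role}_mean"].to_numpy(),
        strategy=pos.strategy,
        manual_threshold=pos.manual_threshold,
    )
    records[f"{role}_positive"] = flags
    logger.info(
        "positivity role=%s strategy=%s threshold=%.6g positives=%d/%d",
        role, pos.strategy, thr, int(flags.sum()), len(flags),
    )
    return records


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured analysis end to end.

    Raises :class:`~spheroquant.errors.ConfigError` on validation failure
    (before touching any input) and
    :class:`~spheroquant.errors.PipelineStageError` if a stage fails, after
    removing partial outputs.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError(
            "invalid pipeline config:\n  - " + "\n  - ".join(violations)
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load_channels"
    try:
        channels = _load_channels(config)
        logger.info("load_channels roles=%s", sorted(channels))

        stage = "nuclei_source"
        nuclei_image = _source_image(channels, config.nuclei_source)

        stage = "identify_nuclei"
        nuclei = segmentation.identify_primary_objects(
            nuclei_image, config.nuclei_params
        )
        logger.info(
            "identify_nuclei objects=%d accepted=%d",
            nuclei.n_objects, len(nuclei.accepted_labels),
        )

        stage = "identify_spheroid"
        sph_source = (
            _source_image(channels, config.spheroid.source)
            if config.spheroid.source
            else nuclei_image
        )
        spheroid = segmentation.identify_spheroid(
            sph_source,
            config.spheroid.diameter_estimate_px,
            threshold_strategy=config.spheroid.threshold_strategy,
            manual_threshold=config.spheroid.manual_threshold,
        )
        logger.info(
            "identify_spheroid equivalent_diameter_px=%.1f",
            spheroid.equivalent_diameter_px,
        )

        stage = "relate_nuclei"
        nuclei_records = spatial.relate_objects(nuclei, spheroid)

        result = PipelineResult(
            out_dir=out_dir,
            nuclei=nuclei,
            spheroid=spheroid,
            nuclei_records=nuclei_records,
        )

        enabled = config.enabled_analyses()

        if "hypoxia" in enabled:
            stage = "hypoxia"
            pimo = channels["pimonidazole"]
            cells = segmentation.identify_secondary_objects(
                nuclei, pimo, config.secondary_params
            )
            cell_records = spatial.relate_objects(cells, spheroid)
            feats = profiles.measure_object_intensity(cells, pimo)
            feats = feats.rename(
                columns={
                    "mean": "pimonidazole_mean",
                    "median": "pimonidazole_median",
                    "integrated": "pimonidazole_integrated",
                }
            )
            cell_records = cell_records.merge(feats, on="object_id", how="left")
            result.cells = cells
            result.cell_records = cell_records
            result.depth_profiles["hypoxia"] = profiles.mean_intensity_profile(
                cell_records, "pimonidazole", config.bin_width_um
            )
            logger.info("hypoxia cells=%d", cells.n_objects)

        if "death" in enabled:
            stage = "death"
            nuclei_records = _measure_and_flag(
                config, nuclei, channels["DRAQ7"], nuclei_records, "DRAQ7"
            )
            result.depth_profiles["death"] = profiles.positive_fraction_profile(
                nuclei_records, "DRAQ7", config.bin_width_um
            )

        if "fucci" in enabled:
            stage = "fucci"
            for role in ("mAG", "mKO2"):
                nuclei_records = _measure_and_flag(
                    config, nuclei, channels[role], nuclei_records, role
                )
            result.depth_profiles["fucci_ratio"] = profiles.ratio_profile(
                nuclei_records,
                numerator_flag="mKO2",
                denominator_flag="mAG",
                bin_width_um=config.bin_width_um,
            )

        if "infiltration" in enabled:
            stage = "infiltration"
            pbmc = segmentation.identify_primary_objects(
                channels["PBMC"], config.pbmc_params
            )
            pbmc_records = spatial.relate_objects(pbmc, spheroid)
            result.pbmc = pbmc
            result.pbmc_records = pbmc_records
            result.depth_profiles["infiltration"] = (
                profiles.infiltration_count_profile(
                    pbmc_records,
                    config.bin_width_um,
                    normalize=config.normalize,
                    spheroid_radius_um=spheroid.equivalent_radius_um,
                )
            )
            logger.info(
                "infiltration pbmc=%d inside=%d",
                pbmc.n_objects,
                int(pbmc_records["inside_spheroid"].sum()),
            )

        result.nuclei_records = nuclei_records

        stage = "write_artefacts"
        written.append(
            image_io.write_object_table(nuclei_records, out_dir / "nuclei.csv")
        )
        if result.cell_records is not None:
            written.append(
                image_io.write_object_table(
                    result.cell_records, out_dir / "cells.csv"
                )
            )
        if result.pbmc_records is not None:
            written.append(
                image_io.write_object_table(
                    result.pbmc_records, out_dir / "pbmc.csv"
                )
            )
        for name, profile in result.depth_profiles.items():
            written.append(
                image_io.write_object_table(
                    profile.to_frame(), out_dir / f"profile_{name}.csv"
                )
            )
            fig, ax = plt.subplots(figsize=(5, 3.2))
            profile.plot(ax=ax)
            fig.tight_layout()
            plot_path = out_dir / f"profile_{name}.png"
            fig.savefig(plot_path)
            plt.close(fig)
            written.append(plot_path)

        overlay = image_io.render_overlay(nuclei_image, nuclei, "outlines")
        written.append(
            image_io.write_overlay(overlay, out_dir / "nuclei_overlay.png")
        )
        sph_labels = LabelMap(
            spheroid.mask.astype("int32"),
            {1: segmentation.ACCEPTED},
            spheroid.pixel_size_um,
        )
        overlay = image_io.render_overlay(sph_source, sph_labels, "outlines")
        written.append(
            image_io.write_overlay(overlay, out_dir / "spheroid_overlay.png")
        )

        snapshot = save_config(config, out_dir / "resolved_config.yaml")
        written.append(snapshot)
        result.written = written
        logger.info("done wrote=%d artefacts", len(written))
        return result
    except ConfigError:
        raise
    except (SpheroquantError, OSError, KeyError, ValueError) as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:  # pragma: no cover - best effort cleanup
                pass
        raise PipelineStageError(stage, exc) from exc
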