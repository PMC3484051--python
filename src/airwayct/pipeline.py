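"""End-to-end orchestration: config, logging, reports.

``run_pipeline`` chains the full analysis — optional HU calibration, lumen
segmentation, lung segmentation, peribronchial-shell construction,
attenuation summary — and writes masks, a JSON report and a one-row CSV.
Every parameter that affects a number (bands, radius, connectivity, seeds,
exclusion) is echoed into the report, and the run is deterministic for a
fixed config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import AgreementReport, PairedMeasurements, bland_altman
from .segmentation import (LUMEN_BAND, LUNG_BAND, SeedPoint, ThresholdBand,
                           auto_seed, segment_lumen, segment_lung)
from .shell_metrics import (DEFAULT_DILATION_RADIUS, AttenuationSummary,
                            ShellParams, peribronchial_shell, summarize)
from .volume_io import (CalibrationStandards, CTVolume, VoxelMask,
                        calibrate_to_hu, read_mask, read_standards_csv,
                        read_volume, write_mask)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "run_agreement"]

logger = logging.getLogger("airwayct")


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    ``input_path`` may be omitted when a :class:`CTVolume` is passed to
    :func:`run_pipeline` directly (e.g. a freshly generated phantom).
    """

    input_path: Optional[str] = None
    output_dir: str = "airwayct_out"
    # calibration: None when the input is already in HU
    calibration: Optional[dict] = None          # {air_raw, water_raw[, bone_raw]} or {csv: path}
    lumen_seeds: Sequence[tuple[int, int, int]] = ()
    lung_seeds: Sequence[tuple[int, int, int]] = ()
    auto_seed_lumen: bool = False
    lumen_band: tuple[float, float] = (LUMEN_BAND.lo, LUMEN_BAND.hi)
    lung_band: tuple[float, float] = (LUNG_BAND.lo, LUNG_BAND.hi)
    connectivity: str = "face6"
    dilation_radius_voxels: float = DEFAULT_DILATION_RADIUS
    dilation_mode: str = "euclidean"
    restrict_shell_to_lung: bool = False
    exclusion_mask_path: Optional[str] = None
    write_masks: bool = True
    log_level: str = "INFO"
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        ThresholdBand(*self.lumen_band)
        ThresholdBand(*self.lung_band)
        if self.dilation_radius_voxels <= 0:
            raise ValueError("dilation_radius_voxels must be > 0")
        for p in (self.input_path, self.exclusion_mask_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if not self.lumen_seeds and not self.auto_seed_lumen:
            raise ValueError("provide lumen_seeds or set auto_seed_lumen: true")
        if not self.lung_seeds:
            raise ValueError("provide lung_seeds")


@dataclass
class PipelineReport:
    """Run summary plus the complete parameter echo that reproduces it."""

    summary: AttenuationSummary
    parameters: dict
    mask_voxels: dict
    software_version: str
    input_checksums: dict

    def as_dict(self) -> dict:
        return {
            "summary": self.summary.as_dict(),
            "parameters": self.parameters,
            "mask_voxels": self.mask_voxels,
            "software_version": self.software_version,
            "input_checksums": self.input_checksums,
        }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_calibration(block: dict) -> CalibrationStandards:
    if "csv" in block:
        return read_standards_csv(block["csv"])
    return CalibrationStandards(
        air_raw=float(block["air_raw"]), water_raw=float(block["water_raw"]),
        bone_raw=float(block["bone_raw"]) if block.get("bone_raw") is not None else None,
    )


def run_pipeline(config: PipelineConfig, volume: Optional[CTVolume] = None,
                 exclusion: Optional[VoxelMask] = None) -> PipelineReport:
    """Execute calibrate → segment lumen → segment lung → shell → summarize.

    Outputs (masks, ``report.json``, ``summary.csv``) land in
    ``config.output_dir``.  Stage failures abort with the stage named in the
    error.  Deterministic: identical config and inputs give byte-identical
    CSV output.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if volume is None:
        config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    checksums: dict[str, str] = {}
    try:
        if volume is None:
            assert config.input_path is not None
            volume = read_volume(config.input_path)
            checksums[config.input_path] = _sha256(config.input_path)
    except Exception as err:
        raise RuntimeError(f"stage 'read': {err}") from err

    try:
        if config.calibration is not None:
            standards = _load_calibration(config.calibration)
            volume = calibrate_to_hu(volume, standards)
        elif not volume.hu_calibrated:
            raise ValueError("input is not HU-calibrated and no calibration block given")
    except Exception as err:
        raise RuntimeError(f"stage 'calibrate': {err}") from err

    lumen_band = ThresholdBand(*config.lumen_band)
    lung_band = ThresholdBand(*config.lung_band)

    try:
        seeds = [SeedPoint(tuple(s)) for s in config.lumen_seeds]
        if config.auto_seed_lumen and not seeds:
            seeds = [auto_seed(volume, lumen_band, config.connectivity)]
        lumen = segment_lumen(volume, seeds, lumen_band, config.connectivity)
        logger.info("lumen: %d voxels", lumen.voxel_count)
    except Exception as err:
        raise RuntimeError(f"stage 'segment_lumen': {err}") from err

    try:
        lung = segment_lung(volume, [SeedPoint(tuple(s)) for s in config.lung_seeds],
                            lung_band, config.connectivity)
        logger.info("lung: %d voxels", lung.voxel_count)
    except Exception as err:
        raise RuntimeError(f"stage 'segment_lung': {err}") from err

    try:
        if exclusion is None and config.exclusion_mask_path is not None:
            exclusion = read_mask(config.exclusion_mask_path, grid=volume)
            checksums[config.exclusion_mask_path] = _sha256(config.exclusion_mask_path)
        params = ShellParams(
            dilation_radius_voxels=config.dilation_radius_voxels,
            lumen_band=lumen_band, dilation_mode=config.dilation_mode,
            restrict_shell_to_lung=config.restrict_shell_to_lung,
            exclusion_applied=exclusion is not None,
        )
        shell = peribronchial_shell(volume, lumen, params, exclusion=exclusion, lung=lung)
        logger.info("shell: %d voxels", shell.voxel_count)
    except Exception as err:
        raise RuntimeError(f"stage 'peribronchial_shell': {err}") from err

    try:
        summary = summarize(volume, lung, shell)
    except Exception as err:
        raise RuntimeError(f"stage 'summarize': {err}") from err

    parameters = {
        "lumen_band_hu": list(config.lumen_band),
        "lung_band_hu": list(config.lung_band),
        "connectivity": config.connectivity,
        "lumen_seeds": [list(s.index) for s in seeds],
        "lung_seeds": [list(s) for s in config.lung_seeds],
        "dilation_radius_voxels": config.dilation_radius_voxels,
        "dilation_mode": config.dilation_mode,
        "restrict_shell_to_lung": config.restrict_shell_to_lung,
        "exclusion_applied": exclusion is not None,
        "calibration": config.calibration,
        "rng_seed": config.rng_seed,
    }
    report = PipelineReport(
        summary=summary,
        parameters=parameters,
        mask_voxels={"lumen": lumen.voxel_count, "lung": lung.voxel_count,
                     "shell": shell.voxel_count},
        software_version=__version__,
        input_checksums=checksums,
    )

    if config.write_masks:
        write_mask(lumen, outdir / "lumen_mask.nii.gz")
        write_mask(lung, outdir / "lung_mask.nii.gz")
        write_mask(shell, outdir / "shell_mask.nii.gz")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    pd.DataFrame([summary.as_dict()]).to_csv(outdir / "summary.csv", index=False)
    return report


def run_agreement(pairs_csv: str | Path, output_dir: Optional[str | Path] = None
                  ) -> AgreementReport:
    """Bland–Altman agreement analysis from a CSV of paired measurements.

    The CSV is long-format with columns ``id,method,value`` (exactly two
    method labels).  Writes ``agreement.json`` and the Bland–Altman plot
    data ``bland_altman.csv`` (columns mean, difference) when
    ``output_dir`` is given.
    """
    try:
        df = pd.read_csv(pairs_csv)
    except Exception as err:
        raise ValueError(f"malformed CSV {pairs_csv}: {err}") from err
    cols = {c.strip().lower() for c in df.columns}
    if not {"id", "method", "value"} <= cols:
        raise ValueError(f"{pairs_csv}: expected columns id,method,value, got {sorted(cols)}")
    df.columns = [c.strip().lower() for c in df.columns]
    methods = sorted(df["method"].unique())
    if len(methods) != 2:
        raise ValueError(f"{pairs_csv}: need exactly two methods, got {methods}")
    wide = df.pivot_table(index="id", columns="method", values="value")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"{pairs_csv}: unpaired ids {missing}")
    pairs = PairedMeasurements(wide[methods[0]].to_numpy(), wide[methods[1]].to_numpy())
    report = bland_altman(pairs)
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "agreement.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame({"mean": report.means, "difference": report.differences}
                     ).to_csv(outdir / "bland_altman.csv", index=False)
    return report
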