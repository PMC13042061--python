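"""Configuration, file I/O and the command-line interface.

Human-edited configuration is YAML (validated strictly: unknown keys are
rejected); machine artifacts are JSON (calibration, provenance), TIFF
(frames, stacks, masks) and CSV (tables, curves).  Every run echoes its
effective configuration and the package version into a provenance record
next to its outputs, and all randomness flows from the config seed.

CLI::

    fovlfm simulate    --config c.yaml --out dir
    fovlfm calibrate   --stack dir --mask m.tif --out cal.json
    fovlfm reconstruct --frame f.tif --mask m.tif --cal cal.json \
                       --zmin 2.0 --zmax 4.0 --zstep 100 --out dir
    fovlfm characterize --config c.yaml --out report/
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__, array_model, calibration, phantoms, reconstruction, wave_optics
from .array_model import ApertureSpec, ArraySpec, DepthRange, SensorSpec, default_array

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_frame",
    "read_frame",
    "write_stack",
    "read_stack",
    "write_calibration",
    "read_calibration",
    "run",
    "cli",
]

log = logging.getLogger("fovlfm")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

EXIT_SCHEMA, EXIT_MISSING_INPUT, EXIT_STAGE = 2, 3, 4


class ConfigError(ValueError):
    """Configuration fails schema validation."""


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class StopConfig:
    diameter_um: float = 600.0
    height_mm: float = 2.0


@dataclass(frozen=True)
class SensorConfig:
    pitch_um: float = 1.4
    width_px: int = 2592
    height_px: int = 1944
    channels: int = 1


@dataclass(frozen=True)
class ArrayConfig:
    lens_diameter_um: float = 370.0
    ring_radius_um: float = 370.0
    tilt_deg: float = 7.057
    intersection_mm: float = 3.0
    sensor_mm: float = 3.0
    central_focal_um: tuple[float, float] = (1250.0, 1750.0)
    edge_focal_um: tuple[float, float] = (1500.0, 2000.0)
    stop: StopConfig = field(default_factory=StopConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)

    def build(self) -> ArraySpec:
        return default_array(
            lens_diameter=self.lens_diameter_um,
            ring_radius=self.ring_radius_um,
            tilt_angle=self.tilt_deg,
            intersection_mm=self.intersection_mm,
            sensor_mm=self.sensor_mm,
            central_focal=tuple(self.central_focal_um),
            edge_focal=tuple(self.edge_focal_um),
            sensor=SensorSpec(self.sensor.pitch_um, self.sensor.width_px,
                              self.sensor.height_px, self.sensor.channels),
            stop=ApertureSpec(self.stop.diameter_um, self.stop.height_mm * 1000.0),
        )


@dataclass(frozen=True)
class PhantomConfig:
    kind: str = "psf_stack"            # psf_stack | beads | grid
    seed: int = 0
    n_layers: int = 3
    beads_per_layer: int = 8
    layer_spacing_um: float = 170.0
    bead_diameter_um: float = 15.4
    lateral_extent_um: float = 500.0
    grid_pitch_um: float = 100.0
    grid_z_mm: float = 3.0
    noise_photon_scale: float = 0.0
    noise_read_sigma: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    z_min_mm: float = 2.0
    z_max_mm: float = 4.0
    z_step_um: float = 100.0
    background_radius_px: float = 50.0
    feature_window_px: int = 31
    feature_opening_px: int = 2
    mask_mode: str = "feature"
    focus_measure: str = "var_laplacian"
    translation_model: str = "piecewise"
    foveated_min: int = 6
    blend_min: int = 3

    def depth_range(self) -> DepthRange:
        return DepthRange(self.z_min_mm * 1000.0, self.z_max_mm * 1000.0,
                          self.z_step_um)


@dataclass(frozen=True)
class RunConfig:
    array: ArrayConfig = field(default_factory=ArrayConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    version: str = "1"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path_or_dict) -> RunConfig:
    """Load + strictly validate a YAML config file (or an equivalent dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_dict)
    if not isinstance(data, dict):
        raise ConfigError("top level must be a mapping")
    unknown = set(data) - {"array", "phantom", "pipeline", "version"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    array_data = dict(data.get("array", {}))
    stop = _from_mapping(StopConfig, array_data.pop("stop", {}), "array.stop")
    sensor = _from_mapping(SensorConfig, array_data.pop("sensor", {}), "array.sensor")
    for key in ("central_focal_um", "edge_focal_um"):
        if key in array_data:
            array_data[key] = tuple(array_data[key])
    arr = _from_mapping(ArrayConfig, {**array_data, "stop": stop, "sensor": sensor},
                        "array")
    phan = _from_mapping(PhantomConfig, data.get("phantom", {}), "phantom")
    pipe = _from_mapping(PipelineConfig, data.get("pipeline", {}), "pipeline")
    return RunConfig(arr, phan, pipe, str(data.get("version", "1")))


# ---------------------------------------------------------------------------
# artifact I/O
# ---------------------------------------------------------------------------

def write_frame(path, frame: phantoms.CaptureFrame, dtype=None) -> None:
    """Frame as TIFF plus a JSON sidecar with metadata and pixel pitch."""
    path = Path(path)
    img = frame.image if dtype is None else frame.image.astype(dtype)
    tifffile.imwrite(path, img)
    sidecar = {"pixel_pitch_um": frame.pixel_pitch, "metadata": frame.metadata}
    path.with_suffix(".json").write_text(json.dumps(sidecar, default=_jsonable))


def read_frame(path) -> phantoms.CaptureFrame:
    path = Path(path)
    img = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    pitch, meta = 1.4, {}
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        pitch = d.get("pixel_pitch_um", pitch)
        meta = d.get("metadata", {})
    return phantoms.CaptureFrame(np.asarray(img), pitch, meta)


def write_stack(path, data: np.ndarray, zs=None, pixel_pitch=None) -> None:
    """Multi-page TIFF, one page per z layer, with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(data))
    side = {"zs_um": None if zs is None else [float(z) for z in zs],
            "pixel_pitch_um": pixel_pitch}
    path.with_suffix(".json").write_text(json.dumps(side))


def read_stack(path) -> tuple[np.ndarray, np.ndarray | None]:
    path = Path(path)
    data = tifffile.imread(path)
    zs = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        if d.get("zs_um"):
            zs = np.asarray(d["zs_um"], dtype=float)
    return np.asarray(data), zs


def write_calibration(path, model: calibration.TranslationModel,
                      mag: calibration.MagnificationModel) -> None:
    Path(path).write_text(
        json.dumps(
            {"translation": model.to_dict(), "magnification": mag.to_dict()},
            indent=2,
        )
    )


def read_calibration(path):
    d = json.loads(Path(path).read_text())
    return (
        calibration.TranslationModel.from_dict(d["translation"]),
        calibration.MagnificationModel.from_dict(d["magnification"]),
    )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_provenance(outdir: Path, config: RunConfig, extra: dict | None = None):
    rec = {"package": "fovlfm", "version": __version__,
           "config": config.to_dict(), **(extra or {})}
    (outdir / "provenance.json").write_text(json.dumps(rec, indent=2,
                                                       default=_jsonable))


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------

def _timer(name):
    class _T:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2f s", name, time.time() - self.t0)

    return _T()


def simulate_run(config: RunConfig, outdir) -> list[Path]:
    """Render phantom frames (plus the aperture frame) with ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    array = config.array.build()
    pc = config.phantom
    noise = None
    if pc.noise_photon_scale > 0 or pc.noise_read_sigma > 0:
        noise = phantoms.NoiseModel(pc.noise_photon_scale, pc.noise_read_sigma,
                                    seed=pc.seed)
    written = []
    with _timer("simulate"):
        ap = phantoms.render_aperture_frame(array)
        write_frame(outdir / "aperture.tif", ap)
        written.append(outdir / "aperture.tif")
        if pc.kind == "psf_stack":
            zr = config.pipeline.depth_range()
            for i, (z, scene) in enumerate(phantoms.psf_calibration_stack_scene(zr)):
                frame = phantoms.render_capture(scene, array, noise=noise)
                frame.metadata["z_um"] = z
                p = outdir / f"psf_{i:03d}.tif"
                write_frame(p, frame)
                written.append(p)
        elif pc.kind == "beads":
            scene = phantoms.bead_layers_phantom(
                pc.n_layers, pc.beads_per_layer, pc.layer_spacing_um,
                pc.bead_diameter_um, pc.lateral_extent_um, seed=pc.seed,
            )
            frame = phantoms.render_capture(scene, array, noise=noise)
            frame.metadata["ground_truth"] = [
                {"position": list(e.position), "diameter": e.diameter}
                for e in scene.emitters
            ]
            p = outdir / "beads.tif"
            write_frame(p, frame)
            written.append(p)
        elif pc.kind == "grid":
            scene = phantoms.grid_target_scene(pc.grid_pitch_um,
                                               z=pc.grid_z_mm * 1000.0)
            frame = phantoms.render_capture(scene, array, noise=noise)
            frame.metadata["z_um"] = pc.grid_z_mm * 1000.0
            p = outdir / "grid.tif"
            write_frame(p, frame)
            written.append(p)
        else:
            raise ConfigError(f"unknown phantom kind {pc.kind!r}")
    _write_provenance(outdir, config, {"command": "simulate"})
    return written


def calibrate_run(stack_dir, mask_path, out_path,
                  config: RunConfig | None = None) -> None:
    """Segment the aperture frame, localize PSFs, fit the calibration models."""
    config = config or RunConfig()
    stack_dir = Path(stack_dir)
    frames = sorted(stack_dir.glob("psf_*.tif"))
    if not frames:
        raise FileNotFoundError(f"no psf_*.tif frames in {stack_dir}")
    with _timer("calibrate"):
        mask = calibration.segment_apertures(read_frame(mask_path))
        stack = []
        for p in frames:
            fr = read_frame(p)
            stack.append((float(fr.metadata["z_um"]), fr))
        locs = calibration.localize_psfs(stack, mask)
        model = calibration.fit_translation_model(
            locs, model=config.pipeline.translation_model
        )
        mag = calibration.fit_magnification(
            "parametric", sensor_distance=config.array.sensor_mm * 1000.0
        )
        write_calibration(out_path, model, mag)
        locs.to_csv(Path(out_path).with_suffix(".localizations.csv"), index=False)


def reconstruct_run(frame_path, mask_path, cal_path, outdir,
                    config: RunConfig | None = None) -> None:
    """Five-stage reconstruction of one frame into a volume + zone stacks."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pipe = config.pipeline
    with _timer("reconstruct"):
        frame = read_frame(frame_path)
        mask = calibration.segment_apertures(read_frame(mask_path))
        model, mag = read_calibration(cal_path)
        zs = pipe.depth_range().samples()
        vol = reconstruction.reconstruct(
            frame, mask, model, mag, zs,
            background_radius=pipe.background_radius_px or None,
            feature_window=pipe.feature_window_px,
            feature_opening=pipe.feature_opening_px,
            mask_mode=pipe.mask_mode,
        )
        write_stack(outdir / "volume.tif", vol.volume.astype(np.float32), vol.zs,
                    vol.object_pixel)
        if vol.shading is not None:
            write_stack(outdir / "shading.tif", vol.shading, vol.zs)
        if vol.zones is not None:
            write_stack(outdir / "zones.tif", vol.zones, vol.zs)
    _write_provenance(outdir, config,
                      {"command": "reconstruct", **vol.provenance})


def characterize_run(config: RunConfig, outdir, edof_grid_n: int = 1024,
                     edof_z_step: float = 50.0) -> dict:
    """Geometry/optics report: NA, detection range, magnification, FOV, EDOF."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    array = config.array.build()
    center = array.lenslet(array.center_lenslet_id)
    edge = array.lenslet(2)
    zr = config.pipeline.depth_range()
    with _timer("characterize"):
        z_near, z_far = array_model.conjugate_object_range(
            center, array.sensor_distance
        )
        report = {
            "edge_lenslet_na": array_model.lenslet_na(edge),
            "central_lenslet_na": array_model.lenslet_na(center),
            "detection_range_mm": [z_near / 1000.0, z_far / 1000.0],
            "detection_span_mm": (z_far - z_near) / 1000.0,
            "mean_magnification": array_model.mean_magnification(
                array, zr.z_min, zr.z_max
            ),
            "axis_convergence_um": array.axis_convergence_error(),
        }
        table, means = array_model.zone_extents(array, zr)
        report["zone_mean_diameters_um"] = means
        table.to_csv(outdir / "zone_extents.csv", index=False)
        ratio = wave_optics.edof_ratio(array, grid_n=edof_grid_n,
                                       z_step=edof_z_step)
        report["edof_ratio"] = ratio
    (outdir / "characterization.json").write_text(
        json.dumps(report, indent=2, default=_jsonable)
    )
    lines = [f"{k}: {v}" for k, v in report.items()]
    (outdir / "characterization.txt").write_text("\n".join(lines) + "\n")
    _write_provenance(outdir, config, {"command": "characterize"})
    return report


def run(command: str, config: RunConfig, **kwargs) -> int:
    """Programmatic entry point mirroring the CLI; returns an exit status."""
    try:
        if command == "simulate":
            simulate_run(config, kwargs["out"])
        elif command == "calibrate":
            calibrate_run(kwargs["stack"], kwargs["mask"], kwargs["out"], config)
        elif command == "reconstruct":
            reconstruct_run(kwargs["frame"], kwargs["mask"], kwargs["cal"],
                            kwargs["out"], config)
        elif command == "characterize":
            characterize_run(config, kwargs["out"])
        else:
            raise ConfigError(f"unknown command {command!r}")
    except ConfigError as exc:
        log.error("config error: %s", exc)
        return EXIT_SCHEMA
    except FileNotFoundError as exc:
        log.error("missing input: %s", exc)
        return EXIT_MISSING_INPUT
    except Exception as exc:
        log.error("stage failure: %s", exc)
        return EXIT_STAGE
    return 0


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

import click  # noqa: E402


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Debug logging.")
@click.option("-q", "--quiet", is_flag=True, help="Errors only.")
def cli(verbose, quiet):
    """Foveated light-field compound imager: simulate, calibrate, reconstruct."""
    if verbose:
        log.setLevel(logging.DEBUG)
    elif quiet:
        log.setLevel(logging.ERROR)


def _load_config_or_exit(path):
    try:
        return load_config(path) if path else RunConfig()
    except ConfigError as exc:
        log.error("config error: %s", exc)
        sys.exit(EXIT_SCHEMA)


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--out", required=True, type=click.Path())
def simulate(config, out):
    """Render synthetic phantom frames with ground-truth sidecars."""
    sys.exit(run("simulate", _load_config_or_exit(config), out=out))


@cli.command()
@click.option("--stack", required=True, type=click.Path(exists=True))
@click.option("--mask", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--config", type=click.Path(exists=True), default=None)
def calibrate(stack, mask, out, config):
    """Fit translation + magnification models from a PSF z-stack."""
    sys.exit(run("calibrate", _load_config_or_exit(config),
                 stack=stack, mask=mask, out=out))


@cli.command()
@click.option("--frame", required=True, type=click.Path(exists=True))
@click.option("--mask", required=True, type=click.Path(exists=True))
@click.option("--cal", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
@click.option("--zmin", type=float, default=None, help="mm")
@click.option("--zmax", type=float, default=None, help="mm")
@click.option("--zstep", type=float, default=None, help="μm")
@click.option("--config", type=click.Path(exists=True), default=None)
def reconstruct(frame, mask, cal, out, zmin, zmax, zstep, config):
    """Reconstruct a volume from one capture frame."""
    cfg = _load_config_or_exit(config)
    if zmin or zmax or zstep:
        pipe = dataclasses.replace(
            cfg.pipeline,
            z_min_mm=zmin or cfg.pipeline.z_min_mm,
            z_max_mm=zmax or cfg.pipeline.z_max_mm,
            z_step_um=zstep or cfg.pipeline.z_step_um,
        )
        cfg = dataclasses.replace(cfg, pipeline=pipe)
    sys.exit(run("reconstruct", cfg, frame=frame, mask=mask, cal=cal, out=out))


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--out", required=True, type=click.Path())
def characterize(config, out):
    """Write the NA / FOV / EDOF / magnification report."""
    sys.exit(run("characterize", _load_config_or_exit(config), out=out))
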