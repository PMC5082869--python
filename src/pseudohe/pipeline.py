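"""End-to-end rendering pipeline: files + config in, virtual H&E out.

Order of operations is fixed: 16-bit normalization → flat-field correction →
RMS demodulation (SIM mode only) → mosaic assembly → gamma compression and
channel balance → RGB mapping → export.  The run configuration is a single
YAML file validated field-by-field; every run writes a JSON report of the
parameters actually used (including auto-estimated balance coefficients), so
a run is reproducible from its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .core import (
    AcquisitionMode,
    Channel,
    ChannelImage,
    ChannelOptics,
    FlatFieldCalibration,
    MosaicLayout,
    OpticsConfig,
    RenderParams,
    SCALE_A_RANGE,
    SCALE_B_RANGE,
    normalize_16bit,
)
from .io import calibration_filename, read_frame, read_frameset
from .mosaic import assemble
from .optics import DEFOCUS_CONSTANT, channel_axial_response, hwhm, normalized_frequency
from .preprocess import _compress, compress_channel, estimate_balance, flatfield_correct
from .pseudocolor import (
    PseudoHEImage,
    green_magenta_composite,
    map_rgb,
    write_png_preview,
    write_rgb_tiff,
)
from .simrecon import rms_demodulate

__all__ = [
    "RunConfig",
    "RenderResult",
    "load_config",
    "render_channels",
    "run_render",
    "run_optics_report",
]

log = logging.getLogger("pseudohe")

_RGB3 = tuple[float, float, float]


class LayoutSection(BaseModel):
    n_rows: int = Field(1, ge=1)
    n_cols: int = Field(1, ge=1)
    overlap_px: tuple[int, int] = (0, 0)

    @field_validator("overlap_px")
    @classmethod
    def _nonneg(cls, v):
        if v[0] < 0 or v[1] < 0:
            raise ValueError("overlap_px entries must be non-negative")
        return v


class RenderSection(BaseModel):
    gamma_d5: float = Field(0.85, ge=0.65, le=1.0)
    gamma_e: float = Field(0.75, ge=0.65, le=1.0)
    #: None means: estimate from the data (Otsu-foreground mean matching).
    scale_a: float | None = Field(None, ge=SCALE_A_RANGE[0], le=SCALE_A_RANGE[1])
    scale_b: float | None = Field(None, ge=SCALE_B_RANGE[0], le=SCALE_B_RANGE[1])
    d5_rgb: _RGB3 = (0.24, 0.21, 0.62)
    e_rgb: _RGB3 = (0.88, 0.27, 0.66)

    @field_validator("d5_rgb", "e_rgb")
    @classmethod
    def _unit_interval(cls, v):
        if any(not (0.0 <= c <= 1.0) for c in v):
            raise ValueError("RGB coefficients must lie in [0, 1]")
        return v


class ChannelOpticsSection(BaseModel):
    lambda_ex_nm: float = Field(gt=0)
    lambda_em_band_nm: tuple[float, float]
    lambda_em_center_nm: float | None = None

    def to_channel_optics(self) -> ChannelOptics:
        return ChannelOptics(
            self.lambda_ex_nm, tuple(self.lambda_em_band_nm), self.lambda_em_center_nm
        )


class OpticsSection(BaseModel):
    grid_freq_cycles_per_mm: float = Field(17.1, gt=0)
    numerical_aperture: float = Field(0.45, gt=0, le=1.5)
    immersion_index: float = Field(1.0, ge=1.0)
    channels: dict[Literal["d5", "e"], ChannelOpticsSection] = Field(
        default_factory=lambda: {
            "d5": ChannelOpticsSection(lambda_ex_nm=630, lambda_em_band_nm=(665, 780)),
            "e": ChannelOpticsSection(lambda_ex_nm=470, lambda_em_band_nm=(530, 620)),
        }
    )

    def to_optics_config(self) -> OpticsConfig:
        return OpticsConfig(
            grid_freq_cycles_per_mm=self.grid_freq_cycles_per_mm,
            numerical_aperture=self.numerical_aperture,
            immersion_index=self.immersion_index,
            channels={
                Channel(k): v.to_channel_optics() for k, v in self.channels.items()
            },
        )


class OutputSection(BaseModel):
    write_channels: bool = True
    write_preview: bool = True
    write_fluorescence_composite: bool = True
    write_widefield: bool = False  # SIM mode: also export the phase-average mosaic


class RunConfig(BaseModel):
    """Validated run configuration (one YAML file per acquisition)."""

    mode: Literal["sim", "widefield"] = "sim"
    frames_dir: str = "."
    pixel_size_um: float = Field(0.635, gt=0)
    layout: LayoutSection = Field(default_factory=LayoutSection)
    calibration: dict[Literal["d5", "e"], str] = Field(
        default_factory=lambda: {
            "d5": calibration_filename(Channel.D5),
            "e": calibration_filename(Channel.E),
        }
    )
    render: RenderSection = Field(default_factory=RenderSection)
    optics: OpticsSection = Field(default_factory=OpticsSection)
    output: OutputSection = Field(default_factory=OutputSection)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def render_channels(
    d5_mosaic: np.ndarray,
    e_mosaic: np.ndarray,
    params: RenderParams,
    scale_a: float | None = None,
    scale_b: float | None = None,
    pixel_size_um: float = 0.635,
) -> tuple[PseudoHEImage, dict]:
    """Compress, balance and RGB-map two intensity-corrected mosaics.

    ``scale_a``/``scale_b`` of None are estimated from the gamma-compressed
    mosaics; supplied values are honored as given.  Returns the rendered
    image and the parameters actually applied.
    """
    d5 = ChannelImage(np.clip(d5_mosaic, 0.0, 1.0), Channel.D5, pixel_size_um)
    e = ChannelImage(np.clip(e_mosaic, 0.0, 1.0), Channel.E, pixel_size_um)
    d5_c = compress_channel(d5, params.gamma_d5, 1.0)
    e_c = compress_channel(e, params.gamma_e, 1.0)
    auto = scale_a is None or scale_b is None
    if auto:
        est_a, est_b = estimate_balance(d5_c, e_c)
        scale_a = est_a if scale_a is None else scale_a
        scale_b = est_b if scale_b is None else scale_b
    d5_final = _compress(d5_c.pixels, 1.0, scale_a)
    e_final = _compress(e_c.pixels, 1.0, scale_b)
    image = map_rgb(d5_final, e_final, params)
    used = {
        "gamma_d5": params.gamma_d5,
        "gamma_e": params.gamma_e,
        "scale_a": float(scale_a),
        "scale_b": float(scale_b),
        "balance": "auto" if auto else "manual",
        "d5_rgb": list(params.d5_rgb),
        "e_rgb": list(params.e_rgb),
    }
    return image, used


@dataclass
class RenderResult:
    out_dir: Path
    rgb_path: Path
    image: PseudoHEImage
    mosaics: dict[Channel, np.ndarray]
    widefield_mosaics: dict[Channel, np.ndarray]
    report: dict


def _channel_mosaic(
    frames_dir: Path,
    channel: Channel,
    mode: AcquisitionMode,
    layout: MosaicLayout,
    calibration: FlatFieldCalibration,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Sectioned (or widefield-passthrough) mosaic for one channel.

    Returns ``(mosaic, widefield_mosaic)``; the second is None outside SIM
    mode.
    """
    tiles = []
    wf_tiles = []
    for position in layout.positions():
        fs = read_frameset(frames_dir, channel, position, mode)
        if fs.frame_shape != layout.frame_shape:
            raise ValueError(
                f"frame at {position} has shape {fs.frame_shape}; layout expects "
                f"{layout.frame_shape}"
            )
        corrected = [
            flatfield_correct(normalize_16bit(f), calibration) for f in fs.frames
        ]
        if mode is AcquisitionMode.SIM:
            sect = rms_demodulate(corrected)
            tiles.append((position, sect.sectioned))
            wf_tiles.append((position, sect.widefield))
        else:
            tiles.append((position, corrected[0]))
    mosaic = assemble(tiles, layout)
    widefield = assemble(wf_tiles, layout) if wf_tiles else None
    return mosaic, widefield


def run_render(
    config_path: str | Path,
    out_dir: str | Path | None = None,
    scale_a: float | None = None,
    scale_b: float | None = None,
    gamma_d5: float | None = None,
    gamma_e: float | None = None,
    d5_rgb: _RGB3 | None = None,
    e_rgb: _RGB3 | None = None,
) -> RenderResult:
    """Execute the full rendering pipeline for one acquisition.

    Command-line overrides (balance coefficients, RGB coefficient tables)
    take precedence over the config file.  All outputs plus a JSON run
    report land in ``out_dir`` (default: ``<acquisition>/render``).
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    frames_dir = (config_path.parent / cfg.frames_dir).resolve()
    out_dir = Path(out_dir) if out_dir is not None else frames_dir / "render"
    out_dir.mkdir(parents=True, exist_ok=True)
    mode = AcquisitionMode(cfg.mode)

    params = RenderParams(
        gamma_d5=gamma_d5 if gamma_d5 is not None else cfg.render.gamma_d5,
        gamma_e=gamma_e if gamma_e is not None else cfg.render.gamma_e,
        d5_rgb=tuple(d5_rgb) if d5_rgb is not None else tuple(cfg.render.d5_rgb),
        e_rgb=tuple(e_rgb) if e_rgb is not None else tuple(cfg.render.e_rgb),
    )
    scale_a = scale_a if scale_a is not None else cfg.render.scale_a
    scale_b = scale_b if scale_b is not None else cfg.render.scale_b

    # layout needs the frame shape: probe the first frame of each channel
    probe = read_frame(
        frames_dir / f"{Channel.D5}_pos0_0_phase0.tif"
    )
    layout = MosaicLayout(
        n_rows=cfg.layout.n_rows,
        n_cols=cfg.layout.n_cols,
        frame_shape=probe.shape,
        overlap_px=tuple(cfg.layout.overlap_px),
    )
    log.info("acquisition: mode=%s layout=%dx%d frame=%s", mode,
             layout.n_rows, layout.n_cols, layout.frame_shape)

    mosaics: dict[Channel, np.ndarray] = {}
    widefield: dict[Channel, np.ndarray] = {}
    clip_fractions: dict[str, float] = {}
    for channel in (Channel.D5, Channel.E):
        calib_path = frames_dir / cfg.calibration[channel.value]
        calibration = FlatFieldCalibration.from_raw(read_frame(calib_path), channel)
        mosaic, wf = _channel_mosaic(frames_dir, channel, mode, layout, calibration)
        clip_fractions[channel.value] = float(np.mean(mosaic > 1.0))
        mosaics[channel] = np.clip(mosaic, 0.0, 1.0)
        if wf is not None:
            widefield[channel] = np.clip(wf, 0.0, 1.0)

    image, used = render_channels(
        mosaics[Channel.D5],
        mosaics[Channel.E],
        params,
        scale_a=scale_a,
        scale_b=scale_b,
        pixel_size_um=cfg.pixel_size_um,
    )

    rgb_path = write_rgb_tiff(image, out_dir / "pseudo_he.tif")
    written = [rgb_path.name]
    if cfg.output.write_preview:
        written.append(write_png_preview(image, out_dir / "pseudo_he_preview.png").name)
    if cfg.output.write_channels:
        for channel, mosaic in mosaics.items():
            p = out_dir / f"mosaic_{channel}.tif"
            tifffile.imwrite(p, np.round(mosaic * 65535).astype(np.uint16))
            written.append(p.name)
    if cfg.output.write_widefield:
        for channel, mosaic in widefield.items():
            p = out_dir / f"widefield_{channel}.tif"
            tifffile.imwrite(p, np.round(mosaic * 65535).astype(np.uint16))
            written.append(p.name)
    if cfg.output.write_fluorescence_composite:
        comp = green_magenta_composite(mosaics[Channel.D5], mosaics[Channel.E])
        written.append(
            write_png_preview(comp, out_dir / "fluorescence_green_magenta.png").name
        )

    report = {
        "pseudohe_version": __version__,
        "config": cfg.model_dump(mode="json"),
        "frames_dir": str(frames_dir),
        "mode": str(mode),
        "layout": {
            "n_rows": layout.n_rows,
            "n_cols": layout.n_cols,
            "frame_shape": list(layout.frame_shape),
            "overlap_px": list(layout.overlap_px),
            "mosaic_shape": list(layout.mosaic_shape),
        },
        "parameters_used": used,
        "clip_fraction_after_flatfield": clip_fractions,
        "outputs": written,
    }
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("wrote %s (+%d files) to %s", rgb_path.name, len(written) - 1, out_dir)

    return RenderResult(
        out_dir=out_dir,
        rgb_path=rgb_path,
        image=image,
        mosaics=mosaics,
        widefield_mosaics=widefield,
        report=report,
    )


def write_phantom_acquisition(
    spec,
    directory: str | Path,
    optics: OpticsConfig | None = None,
    mode: str = "sim",
) -> Path:
    """Write a complete synthetic acquisition the pipeline can consume.

    Generates a tissue phantom from ``spec``, simulates its acquisition
    (SIM or widefield), and writes frames, flat-field calibrations, the
    ground-truth stain planes (under ``truth/``) and a ready-to-run
    ``config.yaml``.  Returns the config path.
    """
    from .io import write_acquisition_frames
    from .phantom import (
        PhantomSpec,
        generate_phantom,
        simulate_sim_frames,
        simulate_widefield_frames,
    )

    assert isinstance(spec, PhantomSpec)
    if optics is None:
        optics = OpticsConfig()
    directory = Path(directory)
    scene = generate_phantom(spec)
    simulate = (
        simulate_sim_frames if AcquisitionMode(mode) is AcquisitionMode.SIM
        else simulate_widefield_frames
    )
    acq = simulate(scene.d5_truth, scene.e_truth, spec, optics)
    write_acquisition_frames(directory, acq.framesets, acq.calibrations, acq.layout)

    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, plane in (("d5_truth", scene.d5_truth), ("e_truth", scene.e_truth)):
        tifffile.imwrite(
            truth_dir / f"{name}.tif", np.round(plane * 65535).astype(np.uint16)
        )

    cfg = RunConfig(
        mode=str(AcquisitionMode(mode)),
        pixel_size_um=spec.pixel_size_um,
        layout=LayoutSection(
            n_rows=acq.layout.n_rows,
            n_cols=acq.layout.n_cols,
            overlap_px=acq.layout.overlap_px,
        ),
        optics=OpticsSection(
            grid_freq_cycles_per_mm=optics.grid_freq_cycles_per_mm,
            numerical_aperture=optics.numerical_aperture,
            immersion_index=optics.immersion_index,
        ),
    )
    config_path = directory / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
    return config_path


def run_optics_report(
    optics: OpticsConfig | None = None,
    convention: str = "emission",
    curve_csv: str | Path | None = None,
) -> dict:
    """Normalized frequency and theoretical section thickness per channel.

    Optionally writes the sampled attenuation curves as CSV
    (columns: defocus_um, attenuation_d5, attenuation_e).
    """
    if optics is None:
        optics = OpticsConfig()
    report: dict = {
        "grid_freq_cycles_per_mm": optics.grid_freq_cycles_per_mm,
        "numerical_aperture": optics.numerical_aperture,
        "convention": convention,
        "defocus_constant": DEFOCUS_CONSTANT[convention],
        "channels": {},
    }
    curves = {}
    for channel in (Channel.D5, Channel.E):
        ch = optics.channel_optics(channel)
        curve = channel_axial_response(optics, channel, convention)
        curves[channel] = curve
        report["channels"][channel.value] = {
            "lambda_ex_nm": ch.lambda_ex_nm,
            "lambda_em_center_nm": ch.em_center_nm,
            "nu_excitation": normalized_frequency(
                optics.grid_freq_cycles_per_mm, ch.lambda_ex_nm,
                optics.numerical_aperture,
            ),
            "nu_used": curve.nu,
            "hwhm_um": hwhm(curve),
        }
    if curve_csv is not None:
        z = np.linspace(0.0, 80.0, 401)
        cols = [z] + [
            curves[ch].evaluate(z) for ch in (Channel.D5, Channel.E)
        ]
        header = "defocus_um,attenuation_d5,attenuation_e"
        np.savetxt(curve_csv, np.column_stack(cols), delimiter=",",
                   header=header, comments="")
        report["curve_csv"] = str(curve_csv)
    return report
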