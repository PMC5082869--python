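"""Synthetic two-channel tissue phantom and SIM acquisition simulator.

The phantom emulates the contrast of a DRAQ5 + eosin stained tissue surface:
non-overlapping elliptical nuclei carry signal only in the DRAQ5 plane, a
smooth stromal texture carries signal only in the eosin plane (eosin-negative
nuclei appear as dark holes), and optional gland lumina are empty in both.

The forward model then simulates what the structured-illumination instrument
records: per stage tile and channel, three phase-shifted frames

    I_n = V · g · [ S_focus·(1 + m·cos(2πfx + φ_n))
                  + S_defocus·(1 + m·a(z)·cos(2πfx + φ_n)) ] + noise

where V is the vignetting profile, g a digital gain, m the grid modulation
depth, a(z) the theoretical axial attenuation at the out-of-focus layer's
offset, and the noise is shot noise at a finite photon budget plus Gaussian
read noise.  Frames are quantized to 16 bits, and the matching flat-field
calibration image (V times a constant) is emitted alongside, so a complete
synthetic acquisition can exercise the entire pipeline with known ground
truth.

The model deliberately collapses the axial dimension to one in-focus plane
plus one out-of-focus layer — enough to test the sectioning contract without
volume rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from .core import (
    FULL_SCALE_16BIT,
    AcquisitionMode,
    Channel,
    FlatFieldCalibration,
    MosaicLayout,
    OpticsConfig,
    RawFrameSet,
    SIM_PHASES_RAD,
)
from .optics import channel_axial_response

__all__ = [
    "PhantomSpec",
    "PhantomScene",
    "SimulatedAcquisition",
    "generate_phantom",
    "modulated_frames",
    "simulate_sim_frames",
    "simulate_widefield_frames",
    "vignetting_profile",
]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic tissue and of the instrument simulation.

    Defaults describe a 512×512 scene at the instrument pixel pitch
    (0.635 μm/px), acquired as 2×2 overlapping tiles, with a 10 000-photon
    budget per full-scale pixel.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.635

    # nuclei (DRAQ5 plane)
    n_nuclei: int = 250
    nucleus_major_um: tuple[float, float] = (9.0, 1.5)  # mean, sd of major axis
    nucleus_aspect: tuple[float, float] = (0.6, 0.95)  # minor/major range
    nuclear_intensity: tuple[float, float] = (0.6, 0.95)

    # stroma (eosin plane)
    stroma_scale_um: float = 8.0  # correlation length of the texture
    stroma_level: float = 0.45
    stroma_contrast: float = 0.35

    # gland lumina: empty in both channels
    n_lumina: int = 3
    lumen_radius_um: tuple[float, float] = (15.0, 30.0)

    # instrument forward model
    vignetting_strength: float = 0.15
    modulation_depth: float = 0.6
    defocus_offset_um: float = 40.0
    defocus_intensity: float = 0.25
    defocus_blur_um: float = 8.0
    photon_budget: float = 10_000.0
    read_noise_sigma: float = 0.001
    digital_gain: float = 0.35  # full-scale headroom for the modulated signal
    calibration_level: float = 0.8
    grid_orientation: str = "x"  # modulation along image x or y
    max_saturation_fraction: float = 0.01

    # tiling of the simulated acquisition
    n_rows: int = 2
    n_cols: int = 2
    overlap_px: int = 16

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.n_lumina < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 < self.modulation_depth <= 1.0):
            raise ValueError("modulation depth must lie in (0, 1]")
        if self.grid_orientation not in ("x", "y"):
            raise ValueError("grid_orientation must be 'x' or 'y'")
        if not (0 <= self.vignetting_strength < 1):
            raise ValueError("vignetting_strength must lie in [0, 1)")
        if self.digital_gain <= 0 or self.calibration_level <= 0:
            raise ValueError("digital_gain and calibration_level must be positive")

    def layout(self) -> MosaicLayout:
        """Tile layout whose assembled mosaic matches ``image_shape``."""
        hh, ww = self.image_shape
        ov = self.overlap_px

        def tile(dim: int, n: int) -> int:
            size, rem = divmod(dim + (n - 1) * ov, n)
            if rem:
                raise ValueError(
                    f"scene dimension {dim} not tileable into {n} tiles "
                    f"with overlap {ov}"
                )
            return size

        return MosaicLayout(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            frame_shape=(tile(hh, self.n_rows), tile(ww, self.n_cols)),
            overlap_px=(ov, ov),
        )


@dataclass
class PhantomScene:
    """Ground-truth stain planes in [0, 1] plus the structure masks."""

    d5_truth: np.ndarray
    e_truth: np.ndarray
    masks: dict[str, np.ndarray]  # "nuclei", "stroma", "lumen"


@dataclass
class SimulatedAcquisition:
    """A complete synthetic acquisition: frames, calibrations and layout."""

    framesets: list[RawFrameSet]
    calibrations: dict[Channel, np.ndarray]  # uint16, one per channel
    layout: MosaicLayout
    mode: AcquisitionMode
    #: flat-field-corrected digital scale: a truth value s appears in the
    #: corrected frames as s * frame_scale (vignetting cancelled).
    frame_scale: float
    #: theoretical attenuation a(z) applied to the defocus layer, per channel.
    defocus_attenuation: dict[Channel, float] = field(default_factory=dict)


def _rng_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    scene_ss, frames_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(scene_ss), np.random.default_rng(frames_ss)


def vignetting_profile(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial quadratic illumination falloff, 1 at the center."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) / max(cy, 1.0)) ** 2 + ((xx - cx) / max(cx, 1.0)) ** 2
    return 1.0 - strength * r2 / 2.0


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> PhantomScene:
    """Generate the in-focus ground-truth stain planes and masks.

    Nuclei are non-overlapping ellipses with jittered size, aspect and
    orientation, present only in the DRAQ5 plane; the eosin plane is a
    smoothed random stromal field, zeroed inside nuclei and lumina.
    Identical spec + seed give bit-identical output.
    """
    if rng is None:
        rng, _ = _rng_streams(spec.rng_seed)
    h, w = spec.image_shape
    px = spec.pixel_size_um

    # gland lumina first; nuclei avoid them
    lumen = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_lumina):
        r_um = rng.uniform(*spec.lumen_radius_um)
        r_px = r_um / px
        cy = rng.uniform(r_px, h - r_px) if h > 2 * r_px else h / 2
        cx = rng.uniform(r_px, w - r_px) if w > 2 * r_px else w / 2
        rr, cc = ellipse(
            cy, cx, r_px, r_px * rng.uniform(0.7, 1.0),
            shape=(h, w), rotation=rng.uniform(0, math.pi),
        )
        lumen[rr, cc] = True

    nuclei = np.zeros((h, w), dtype=bool)
    d5 = np.zeros((h, w), dtype=np.float64)
    placed = 0
    max_tries = max(200 * spec.n_nuclei, 1000)
    tries = 0
    while placed < spec.n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not pack {spec.n_nuclei} nuclei into {spec.image_shape} "
                f"(placed {placed} after {max_tries} attempts)"
            )
        major_um = rng.normal(*spec.nucleus_major_um)
        major_um = float(np.clip(major_um, 4.0, 16.0))
        aspect = rng.uniform(*spec.nucleus_aspect)
        a_px = 0.5 * major_um / px
        b_px = a_px * aspect
        cy = rng.uniform(a_px, h - a_px)
        cx = rng.uniform(a_px, w - a_px)
        theta = rng.uniform(0, math.pi)
        rr, cc = ellipse(cy, cx, a_px, b_px, shape=(h, w), rotation=theta)
        # clearance test with grown axes keeps nuclei separated by >= 1 px,
        # so each stays its own connected component
        rr_t, cc_t = ellipse(cy, cx, a_px + 1.5, b_px + 1.5, shape=(h, w),
                             rotation=theta)
        if rr.size == 0 or nuclei[rr_t, cc_t].any() or lumen[rr, cc].any():
            continue
        nuclei[rr, cc] = True
        d5[rr, cc] = rng.uniform(*spec.nuclear_intensity)
        placed += 1

    # stromal texture: smoothed white noise, normalized, then windowed
    noise = rng.standard_normal((h, w))
    sigma_px = spec.stroma_scale_um / px
    smooth = gaussian_filter(noise, sigma=sigma_px, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    e = np.clip(spec.stroma_level + spec.stroma_contrast * smooth * 0.5, 0.05, 0.95)
    e[nuclei] = 0.0  # eosin-negative nuclei
    e[lumen] = 0.0
    d5[lumen] = 0.0
    stroma = ~(nuclei | lumen)

    return PhantomScene(
        d5_truth=d5,
        e_truth=e,
        masks={"nuclei": nuclei, "stroma": stroma, "lumen": lumen},
    )


def _grid_pattern(shape: tuple[int, int], spec: PhantomSpec,
                  f_cycles_per_mm: float, phase: float) -> np.ndarray:
    h, w = shape
    f_per_px = f_cycles_per_mm * 1e-3 * spec.pixel_size_um  # cycles / pixel
    coord = np.arange(w if spec.grid_orientation == "x" else h, dtype=np.float64)
    line = np.cos(2.0 * math.pi * f_per_px * coord + phase)
    if spec.grid_orientation == "x":
        return np.broadcast_to(line, (h, w))
    return np.broadcast_to(line[:, None], (h, w))


def _cut_tiles(scene: np.ndarray, layout: MosaicLayout):
    th, tw = layout.frame_shape
    for pos in layout.positions():
        y0, x0 = layout.origin_of(pos)
        yield pos, scene[y0 : y0 + th, x0 : x0 + tw]


def _add_noise(signal: np.ndarray, spec: PhantomSpec,
               rng: np.random.Generator) -> np.ndarray:
    out = signal
    if spec.photon_budget and np.isfinite(spec.photon_budget):
        out = rng.poisson(np.clip(out, 0, None) * spec.photon_budget) / spec.photon_budget
    if spec.read_noise_sigma > 0:
        out = out + rng.normal(0.0, spec.read_noise_sigma, size=signal.shape)
    return out


def _quantize(signal: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    digital = np.round(np.clip(signal, 0.0, None) * FULL_SCALE_16BIT)
    saturated = np.mean(digital >= FULL_SCALE_16BIT)
    if saturated > spec.max_saturation_fraction:
        raise ValueError(
            f"{saturated:.1%} of pixels saturate the 16-bit range; lower "
            "digital_gain or the photon budget headroom"
        )
    return np.clip(digital, 0, FULL_SCALE_16BIT).astype(np.uint16)


def _defocus_layer(truth: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.defocus_intensity <= 0:
        return np.zeros_like(truth)
    sigma_px = spec.defocus_blur_um / spec.pixel_size_um
    return spec.defocus_intensity * gaussian_filter(truth, sigma=sigma_px, mode="reflect")


def modulated_frames(
    in_focus: np.ndarray,
    spec: PhantomSpec,
    grid_freq_cycles_per_mm: float = 17.1,
    defocus: np.ndarray | None = None,
    attenuation: float = 1.0,
) -> list[np.ndarray]:
    """Noise-free, unquantized 3-phase forward model of one tile.

    Returns the three float frames
    ``in_focus·(1 + m·cos(2πfx + φ_n)) + defocus·(1 + m·a·cos(2πfx + φ_n))``;
    the RMS demodulator recovers ``m·(in_focus + a·defocus)`` from them
    exactly, which makes closed-form round-trip tests possible before noise
    and 16-bit quantization enter.
    """
    in_focus = np.asarray(in_focus, dtype=np.float64)
    out = []
    for phase in SIM_PHASES_RAD:
        grid = _grid_pattern(in_focus.shape, spec, grid_freq_cycles_per_mm, phase)
        frame = in_focus * (1.0 + spec.modulation_depth * grid)
        if defocus is not None:
            frame = frame + np.asarray(defocus, dtype=np.float64) * (
                1.0 + spec.modulation_depth * attenuation * grid
            )
        out.append(frame)
    return out


def simulate_sim_frames(
    d5_truth: np.ndarray,
    e_truth: np.ndarray,
    spec: PhantomSpec,
    optics: OpticsConfig | None = None,
) -> SimulatedAcquisition:
    """Simulate the 3-phase SIM acquisition of a phantom scene.

    Per channel and tile, emits the three phase frames of the forward model
    in the module docstring, 16-bit quantized, plus the matching flat-field
    calibration image (vignetting times a constant).  The out-of-focus
    layer's modulation is attenuated by the optics module's theoretical
    axial response at the layer's offset.
    """
    if optics is None:
        optics = OpticsConfig()
    return _simulate(d5_truth, e_truth, spec, optics, AcquisitionMode.SIM)


def simulate_widefield_frames(
    d5_truth: np.ndarray,
    e_truth: np.ndarray,
    spec: PhantomSpec,
    optics: OpticsConfig | None = None,
) -> SimulatedAcquisition:
    """Simulate the single-frame widefield acquisition (no grid pattern)."""
    if optics is None:
        optics = OpticsConfig()
    return _simulate(d5_truth, e_truth, spec, optics, AcquisitionMode.WIDEFIELD)


def _simulate(
    d5_truth: np.ndarray,
    e_truth: np.ndarray,
    spec: PhantomSpec,
    optics: OpticsConfig,
    mode: AcquisitionMode,
) -> SimulatedAcquisition:
    d5_truth = np.asarray(d5_truth, dtype=np.float64)
    e_truth = np.asarray(e_truth, dtype=np.float64)
    if d5_truth.shape != e_truth.shape:
        raise ValueError("channel truth planes must share shape")
    if d5_truth.shape != tuple(spec.image_shape):
        raise ValueError(
            f"truth shape {d5_truth.shape} does not match spec.image_shape "
            f"{tuple(spec.image_shape)}"
        )
    layout = spec.layout()
    _, rng = _rng_streams(spec.rng_seed)
    vignette = vignetting_profile(layout.frame_shape, spec.vignetting_strength)
    m = spec.modulation_depth
    g = spec.digital_gain

    attenuation: dict[Channel, float] = {}
    framesets: list[RawFrameSet] = []
    calibrations: dict[Channel, np.ndarray] = {}
    for channel, truth in ((Channel.D5, d5_truth), (Channel.E, e_truth)):
        curve = channel_axial_response(optics, channel)
        a_z = float(curve.evaluate(np.asarray([spec.defocus_offset_um]))[0])
        attenuation[channel] = a_z
        defocus = _defocus_layer(truth, spec)
        for (pos, tile_f), (_, tile_d) in zip(
            _cut_tiles(truth, layout), _cut_tiles(defocus, layout)
        ):
            frames = []
            if mode is AcquisitionMode.SIM:
                for phase in SIM_PHASES_RAD:
                    grid = _grid_pattern(layout.frame_shape, spec,
                                         optics.grid_freq_cycles_per_mm, phase)
                    signal = vignette * g * (
                        tile_f * (1.0 + m * grid) + tile_d * (1.0 + m * a_z * grid)
                    )
                    frames.append(_quantize(_add_noise(signal, spec, rng), spec))
            else:
                signal = vignette * g * (tile_f + tile_d)
                frames.append(_quantize(_add_noise(signal, spec, rng), spec))
            framesets.append(
                RawFrameSet(
                    frames=tuple(frames),
                    channel=channel,
                    mode=mode,
                    grid_position=pos,
                )
            )
        calibrations[channel] = np.round(
            np.clip(spec.calibration_level * vignette, 0.0, 1.0) * FULL_SCALE_16BIT
        ).astype(np.uint16)

    return SimulatedAcquisition(
        framesets=framesets,
        calibrations=calibrations,
        layout=layout,
        mode=mode,
        frame_scale=g / spec.calibration_level,
        defocus_attenuation=attenuation,
    )


def calibration_for(acq: SimulatedAcquisition, channel: Channel) -> FlatFieldCalibration:
    """Prepared flat-field calibration object for one simulated channel."""
    return FlatFieldCalibration.from_raw(acq.calibrations[Channel(channel)], channel)
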