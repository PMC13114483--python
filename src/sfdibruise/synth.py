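"""Synthetic structured-illumination scenes of bruised fruit.

This module is the data engine of the package.  Instead of ray tracing, raw
phase-shifted intensity stacks are rendered analytically: every pixel carries
a ground-truth pair of optical transport coefficients (mu_a, mu_s') and its
intensity under sinusoidal illumination is computed in closed form from the
diffusion forward model, so the (image, coefficient-map) pairing is exact by
construction.

Scenes emulate planar or dome-shaped (spherical-cap) turbid samples with
apple-like or pear-like coefficients, a circular subsurface bruise in which
the reduced scattering coefficient drops toward its bruised value, and, for
pears, multiplicative lenticel speckle on mu_s'.  A batch generator sweeps a
coefficient grid to emit the paired training dataset (800 samples by default,
split 7:3 into 560 train / 240 validation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import demod, forward
from .demod import REFERENCE_REFLECTIVITY

__all__ = [
    "OpticalPropertyMap",
    "FruitSceneSpec",
    "PhaseShiftStack",
    "FringeStack",
    "CurvedScene",
    "DatasetManifest",
    "FRUIT_BASE_COEFFS",
    "NORM_RANGES",
    "make_fruit_map",
    "render_stack",
    "render_reference_stack",
    "encode_rgb_label",
    "decode_rgb_label",
    "build_dataset",
    "default_sweep",
    "render_curved_scene",
    "demodulate_scene",
]

#: Mean optical coefficients (mm^-1): (mu_a, mu_s' sound, mu_s' fully bruised).
FRUIT_BASE_COEFFS = {
    "apple": (0.0324, 1.726, 1.215),
    "pear": (0.0418, 2.102, 1.702),
}
#: Bruised-to-sound mu_s' ratio used for generic phantom scenes (apple-like).
PHANTOM_BRUISE_RATIO = 1.215 / 1.726
#: Label normalization ranges in mm^-1: mu_a over [0, 0.5], mu_s' over [0, 4].
NORM_RANGES = (0.5, 4.0)
#: Default simulated field width, mm.
FIELD_WIDTH_MM = 100.0
#: Default illumination offset/modulation and camera gain.
DEFAULT_A0 = 0.5
DEFAULT_A1 = 0.5
DEFAULT_GAIN = 1.0
#: Default additive read noise, as sd in intensity units (0.5% of full scale).
DEFAULT_NOISE_SD = 0.005
#: Three-phase shifts of the AC projection.
AC_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
#: Four-step phases of the fringe projection used for profilometry.
FRINGE_PHASES = (0.0, np.pi / 2.0, np.pi, 3.0 * np.pi / 2.0)


@dataclass
class OpticalPropertyMap:
    """Per-pixel optical transport coefficients, mm^-1."""

    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.mu_s_prime = np.asarray(self.mu_s_prime, dtype=float)
        if self.mu_a.shape != self.mu_s_prime.shape:
            raise ValueError("mu_a and mu_s_prime maps must share a shape")
        if np.any(self.mu_a < 0):
            raise ValueError("mu_a map must be >= 0")
        if np.any(self.mu_s_prime <= 0):
            raise ValueError("mu_s_prime map must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self):
        return self.mu_a.shape


@dataclass(frozen=True)
class FruitSceneSpec:
    """Declarative description of one synthetic fruit scene.

    ``severity`` interpolates mu_s' inside the bruise disc linearly from the
    sound value (0) to the fully bruised value (1).  ``bruise_radius`` is in
    mm; 0 means non-bruised.  ``surface`` is ``"planar"`` or
    ``"spherical_cap"`` (with ``height_max`` in mm).
    """

    fruit_kind: str = "apple"
    base_mu_a: float | None = None
    base_mu_s_prime: float | None = None
    bruise_center: tuple[int, int] | None = None
    bruise_radius: float = 15.0
    severity: float = 1.0
    lenticel_speckle_sd: float = 0.03
    surface: str = "planar"
    height_max: float = 20.0
    size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fruit_kind not in ("apple", "pear", "phantom"):
            raise ValueError(f"unknown fruit_kind {self.fruit_kind!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.bruise_radius < 0:
            raise ValueError("bruise_radius must be >= 0")
        if self.surface not in ("planar", "spherical_cap"):
            raise ValueError(f"unknown surface {self.surface!r}")
        if self.surface == "spherical_cap" and self.height_max <= 0:
            raise ValueError("spherical_cap height_max must be > 0")
        if self.fruit_kind == "phantom" and (
            self.base_mu_a is None or self.base_mu_s_prime is None
        ):
            raise ValueError("phantom scenes require explicit base coefficients")

    @property
    def pixel_size(self) -> float:
        return FIELD_WIDTH_MM / self.size


@dataclass
class PhaseShiftStack:
    """One DC frame plus three AC frames at phases 0, 2pi/3, 4pi/3."""

    I_dc: np.ndarray
    I1: np.ndarray
    I2: np.ndarray
    I3: np.ndarray
    fx_ac: float
    pixel_size: float

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.I_dc, self.I1, self.I2, self.I3)}
        if len(shapes) != 1:
            raise ValueError("all four frames must share a shape")
        for a in (self.I_dc, self.I1, self.I2, self.I3):
            if np.any(a < 0):
                raise ValueError("intensities must be nonnegative")

    @property
    def ac_frames(self):
        return self.I1, self.I2, self.I3


@dataclass
class FringeStack:
    """Four-step fringe images at projector phases 0, pi/2, pi, 3pi/2."""

    F1: np.ndarray
    F2: np.ndarray
    F3: np.ndarray
    F4: np.ndarray
    fringe_freq: float
    pixel_size: float
    reference_phase: np.ndarray = None  # type: ignore[assignment]

    @property
    def frames(self):
        return self.F1, self.F2, self.F3, self.F4


@dataclass
class CurvedScene:
    """Everything a curved-surface correction experiment needs."""

    distorted: PhaseShiftStack
    undistorted: PhaseShiftStack
    fringes: FringeStack
    reference_fringes: FringeStack
    height: np.ndarray
    height_max: float
    c_field: np.ndarray
    footprint: np.ndarray
    scene_map: OpticalPropertyMap
    bruise_mask: np.ndarray
    sound_mask: np.ndarray


@dataclass
class DatasetManifest:
    """Index of the generated paired dataset."""

    entries: list = field(default_factory=list)  # dicts: input/label/gt/split
    seed: int = 0
    sweep: dict = field(default_factory=dict)

    def paths(self, split: str | None = None):
        return [e for e in self.entries if split is None or e["split"] == split]

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"seed": self.seed, "sweep": self.sweep, "entries": self.entries},
                indent=1,
            )
        )

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(entries=d["entries"], seed=d["seed"], sweep=d["sweep"])


def _disc_mask(shape, center, radius_px):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def make_fruit_map(spec: FruitSceneSpec):
    """Build the per-pixel coefficient maps plus bruise/sound region masks.

    Returns ``(OpticalPropertyMap, bruise_mask, sound_mask)`` where the sound
    mask is an equal-area annulus of intact tissue adjacent to the bruise
    disc (outer radius ``radius * sqrt(2)``).
    """
    size = spec.size
    px = spec.pixel_size
    if spec.fruit_kind == "phantom":
        base_mu_a, base_mu_s = spec.base_mu_a, spec.base_mu_s_prime
        bruised_mu_s = PHANTOM_BRUISE_RATIO * base_mu_s
    else:
        mu_a0, mu_s0, mu_s_br = FRUIT_BASE_COEFFS[spec.fruit_kind]
        base_mu_a = spec.base_mu_a if spec.base_mu_a is not None else mu_a0
        base_mu_s = spec.base_mu_s_prime if spec.base_mu_s_prime is not None else mu_s0
        bruised_mu_s = mu_s_br * (base_mu_s / mu_s0)

    mu_a = np.full((size, size), base_mu_a, dtype=float)
    mu_s = np.full((size, size), base_mu_s, dtype=float)

    center = spec.bruise_center if spec.bruise_center is not None else (size // 2, size // 2)
    r_px = spec.bruise_radius / px
    if spec.bruise_radius > 0 and spec.severity > 0:
        r_out = r_px * np.sqrt(2.0)
        if (
            center[0] - r_out < 0
            or center[1] - r_out < 0
            or center[0] + r_out >= size
            or center[1] + r_out >= size
        ):
            raise ValueError("bruise disc (plus sound annulus) exceeds the field")
        bruise_mask = _disc_mask((size, size), center, r_px)
        sound_mask = _disc_mask((size, size), center, r_out) & ~bruise_mask
        mu_s[bruise_mask] = base_mu_s + spec.severity * (bruised_mu_s - base_mu_s)
    else:
        bruise_mask = np.zeros((size, size), dtype=bool)
        sound_mask = ~bruise_mask

    if spec.fruit_kind == "pear" and spec.lenticel_speckle_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.lenticel_speckle_sd
        speckle = rng.lognormal(mean=-0.5 * sd**2, sigma=sd, size=(size, size))
        mu_s = mu_s * speckle

    return OpticalPropertyMap(mu_a=mu_a, mu_s_prime=mu_s, pixel_size=px), bruise_mask, sound_mask


def _render_frames(Rd_dc, Rd_ac, fx_ac, pixel_size, phases, a0, a1, gain, noise_sd, rng):
    """Shared analytic rendering core: DC frame plus phase-shifted AC frames."""
    h, w = Rd_dc.shape
    x_mm = np.arange(w, dtype=float)[None, :] * pixel_size
    frames = []
    I_dc = gain * a0 * Rd_dc
    for psi in phases:
        carrier = np.cos(2.0 * np.pi * fx_ac * x_mm + psi)
        frames.append(gain * (a0 * Rd_dc + a1 * carrier * Rd_ac))
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires a seeded rng")
        I_dc = I_dc + rng.normal(0.0, noise_sd, I_dc.shape)
        frames = [f + rng.normal(0.0, noise_sd, f.shape) for f in frames]
    return np.clip(I_dc, 0.0, None), [np.clip(f, 0.0, None) for f in frames]


def render_stack(
    opmap: OpticalPropertyMap,
    fx_ac: float = forward.DEFAULT_FX_AC,
    a0: float = DEFAULT_A0,
    a1: float = DEFAULT_A1,
    gain: float = DEFAULT_GAIN,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n: float = forward.DEFAULT_N,
    dialect: str = "squared",
) -> PhaseShiftStack:
    """Render the raw four-frame acquisition of a planar scene.

    Per pixel, the DC frame is ``gain * a0 * Rd(0)`` and each AC frame is
    ``gain * (a0 * Rd(0) + a1 * cos(2*pi*fx_ac*x + psi) * Rd(fx_ac))`` with
    Gaussian read noise of sd ``noise_sd`` added and negatives clipped.
    """
    if fx_ac < 0:
        raise ValueError("fx_ac must be >= 0")
    if not a0 >= a1 >= 0:
        raise ValueError("illumination requires a0 >= a1 >= 0")
    Rd_dc = forward.diffuse_reflectance(opmap.mu_a, opmap.mu_s_prime, 0.0, n, dialect)
    Rd_ac = forward.diffuse_reflectance(opmap.mu_a, opmap.mu_s_prime, fx_ac, n, dialect)
    rng = np.random.default_rng(seed) if seed is not None else None
    I_dc, (I1, I2, I3) = _render_frames(
        Rd_dc, Rd_ac, fx_ac, opmap.pixel_size, AC_PHASES, a0, a1, gain, noise_sd, rng
    )
    return PhaseShiftStack(I_dc, I1, I2, I3, fx_ac=fx_ac, pixel_size=opmap.pixel_size)


def render_reference_stack(
    fx_ac: float = forward.DEFAULT_FX_AC,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = FIELD_WIDTH_MM / 256,
    a0: float = DEFAULT_A0,
    a1: float = DEFAULT_A1,
    gain: float = DEFAULT_GAIN,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PhaseShiftStack:
    """Render the standard reflectance reference (Rd = 0.99 at all fx)."""
    if fx_ac < 0:
        raise ValueError("fx_ac must be >= 0")
    Rd = np.full(shape, REFERENCE_REFLECTIVITY)
    rng = np.random.default_rng(seed) if seed is not None else None
    I_dc, (I1, I2, I3) = _render_frames(
        Rd, Rd, fx_ac, pixel_size, AC_PHASES, a0, a1, gain, noise_sd, rng
    )
    return PhaseShiftStack(I_dc, I1, I2, I3, fx_ac=fx_ac, pixel_size=pixel_size)


def demodulate_scene(sample: PhaseShiftStack, reference: PhaseShiftStack):
    """Demodulate and calibrate a sample stack against a reference stack.

    Returns ``(Rd_dc_map, Rd_ac_map)`` as :class:`~sfdibruise.demod.DiffuseReflectanceMap`.
    """
    M_ac = demod.demodulate_ac(*sample.ac_frames, fx=sample.fx_ac)
    M_ac_ref = demod.demodulate_ac(*reference.ac_frames, fx=reference.fx_ac)
    M_dc = demod.demodulate_dc(sample.I_dc)
    M_dc_ref = demod.demodulate_dc(reference.I_dc)
    return demod.calibrate(M_dc, M_dc_ref), demod.calibrate(M_ac, M_ac_ref)


# ---------------------------------------------------------------------------
# RGB label encoding

def encode_rgb_label(opmap: OpticalPropertyMap, norm_ranges=NORM_RANGES) -> np.ndarray:
    """Encode coefficient maps as an 8-bit RGB label image.

    R carries mu_a normalized over ``[0, norm_ranges[0]]``, G carries mu_s'
    over ``[0, norm_ranges[1]]``, B is fixed at zero.  Out-of-range values
    raise rather than clip silently.
    """
    r_max, g_max = norm_ranges
    if np.any(opmap.mu_a > r_max) or np.any(opmap.mu_s_prime > g_max):
        raise ValueError("coefficient values exceed the label normalization ranges")
    label = np.zeros(opmap.shape + (3,), dtype=np.uint8)
    label[..., 0] = np.rint(255.0 * opmap.mu_a / r_max).astype(np.uint8)
    label[..., 1] = np.rint(255.0 * opmap.mu_s_prime / g_max).astype(np.uint8)
    return label


def decode_rgb_label(
    label: np.ndarray, pixel_size: float, norm_ranges=NORM_RANGES
) -> OpticalPropertyMap:
    """Invert :func:`encode_rgb_label` up to 8-bit quantization."""
    label = np.asarray(label)
    if label.ndim != 3 or label.shape[-1] != 3:
        raise ValueError("label must be an HxWx3 image")
    r_max, g_max = norm_ranges
    mu_a = label[..., 0].astype(float) / 255.0 * r_max
    mu_s = label[..., 1].astype(float) / 255.0 * g_max
    # mu_s' = 0 is unphysical; lift decoded zeros to the smallest encodable step
    mu_s = np.maximum(mu_s, g_max / 255.0 / 2.0)
    return OpticalPropertyMap(mu_a=mu_a, mu_s_prime=mu_s, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Batch dataset generation

def default_sweep() -> dict:
    """The default coefficient sweep: 20 mu_a x 10 mu_s' x 4 severities = 800."""
    return {
        "mu_a": np.linspace(0.01, 0.45, 20).tolist(),
        "mu_s_prime": np.linspace(0.4, 3.6, 10).tolist(),
        "severity": [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0],
    }


def build_dataset(
    out_dir,
    seed: int = 0,
    sweep: dict | None = None,
    size: int = 64,
    fx_ac: float = forward.DEFAULT_FX_AC,
    noise_sd: float = DEFAULT_NOISE_SD,
    train_fraction: float = 0.7,
) -> DatasetManifest:
    """Generate the paired (reflectance image, RGB label) training dataset.

    Every sweep point is rendered, demodulated and calibrated; the input is
    the calibrated AC diffuse reflectance image (float TIFF), the label the
    RGB-encoded coefficient maps (PNG), the ground truth a two-page float
    TIFF (mu_a, mu_s').  The shuffled split is deterministic in ``seed``;
    the default 800-point sweep yields 560 train / 240 validation.
    """
    import tifffile
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if sweep is None:
        sweep = default_sweep()
    points = [
        (mu_a, mu_s, sev)
        for mu_a in sweep["mu_a"]
        for mu_s in sweep["mu_s_prime"]
        for sev in sweep["severity"]
    ]
    if len(points) < 1:
        raise ValueError("sweep must contain at least one point")

    rng = np.random.default_rng(seed)
    pixel_size = FIELD_WIDTH_MM / size
    reference = render_reference_stack(
        fx_ac, shape=(size, size), pixel_size=pixel_size,
        noise_sd=noise_sd, seed=int(rng.integers(2**31)),
    )

    manifest = DatasetManifest(seed=seed, sweep={k: list(v) for k, v in sweep.items()})
    n_train = round(train_fraction * len(points))
    order = rng.permutation(len(points))
    split_of = {int(idx): ("train" if rank < n_train else "val") for rank, idx in enumerate(order)}

    for i, (mu_a, mu_s, sev) in enumerate(points):
        spec = FruitSceneSpec(
            fruit_kind="phantom",
            base_mu_a=float(mu_a),
            base_mu_s_prime=float(mu_s),
            severity=float(sev),
            bruise_radius=15.0 if sev > 0 else 0.0,
            size=size,
            seed=int(rng.integers(2**31)),
        )
        opmap, _, _ = make_fruit_map(spec)
        stack = render_stack(
            opmap, fx_ac, noise_sd=noise_sd, seed=int(rng.integers(2**31))
        )
        _, rd_ac = demodulate_scene(stack, reference)
        label = encode_rgb_label(opmap)

        input_path = out_dir / f"sample_{i:04d}_rd.tiff"
        label_path = out_dir / f"sample_{i:04d}_label.png"
        gt_path = out_dir / f"sample_{i:04d}_gt.tiff"
        tifffile.imwrite(input_path, rd_ac.Rd.astype(np.float32))
        Image.fromarray(label, mode="RGB").save(label_path)
        tifffile.imwrite(
            gt_path, np.stack([opmap.mu_a, opmap.mu_s_prime]).astype(np.float32)
        )
        manifest.entries.append(
            {
                "input": input_path.name,
                "label": label_path.name,
                "gt": gt_path.name,
                "split": split_of[i],
                "mu_a": float(mu_a),
                "mu_s_prime": float(mu_s),
                "severity": float(sev),
            }
        )

    manifest.save(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Curved scenes for profile correction

#: Lower clamp of the correction coefficient at the fruit rim.
C_MIN = 0.05


def _spherical_cap_height(size, pixel_size, height_max, footprint_radius_mm):
    """Height of a spherical cap: height_max at center, 0 at the rim."""
    half = (size - 1) / 2.0
    rr, cc = np.mgrid[:size, :size]
    r_mm = np.hypot(rr - half, cc - half) * pixel_size
    R = (footprint_radius_mm**2 + height_max**2) / (2.0 * height_max)
    h = np.zeros((size, size))
    inside = r_mm <= footprint_radius_mm
    h[inside] = np.sqrt(R**2 - r_mm[inside] ** 2) - (R - height_max)
    return np.clip(h, 0.0, height_max), inside


def render_curved_scene(
    spec: FruitSceneSpec,
    fx_ac: float = forward.DEFAULT_FX_AC,
    fringe_freq: float = 0.15,
    k_height: float = 1.0,
    noise_sd: float = 0.0,
    a0: float = DEFAULT_A0,
    a1: float = DEFAULT_A1,
) -> CurvedScene:
    """Render a dome-shaped scene with curvature-induced intensity falloff.

    The raw frames of the planar rendering are multiplied pixelwise by the
    correction coefficient ``c = h / h_max`` (clamped below at ``C_MIN``), so
    the height-derived correction inverts the distortion exactly.  A
    four-step fringe stack is emitted whose phase offset relative to the
    reference plane equals ``h / k_height`` (rad), plus the matching
    reference-plane fringes.
    """
    if spec.surface != "spherical_cap":
        raise ValueError("render_curved_scene requires a spherical_cap surface")
    size = spec.size
    px = spec.pixel_size
    opmap, bruise_mask, sound_mask = make_fruit_map(spec)
    undistorted = render_stack(opmap, fx_ac, a0=a0, a1=a1, noise_sd=0.0)

    footprint_radius_mm = 0.45 * FIELD_WIDTH_MM
    h, footprint = _spherical_cap_height(size, px, spec.height_max, footprint_radius_mm)
    # normalize by the realized peak (the grid may not sample the apex
    # exactly), matching the height-derived correction field downstream
    c = np.clip(h / h.max(), C_MIN, 1.0)

    rng = np.random.default_rng(spec.seed) if noise_sd > 0 else None

    def _noisy(img):
        if rng is None:
            return img
        return np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)

    distorted = PhaseShiftStack(
        _noisy(undistorted.I_dc * c),
        _noisy(undistorted.I1 * c),
        _noisy(undistorted.I2 * c),
        _noisy(undistorted.I3 * c),
        fx_ac=fx_ac,
        pixel_size=px,
    )

    x_mm = np.arange(size, dtype=float)[None, :] * px
    ref_phase = 2.0 * np.pi * fringe_freq * x_mm * np.ones((size, 1))
    phase = ref_phase + h / k_height

    def _fringes(total_phase):
        frames = [
            np.clip(_noisy(a0 + a1 * np.cos(total_phase + psi)), 0.0, None)
            for psi in FRINGE_PHASES
        ]
        return FringeStack(*frames, fringe_freq=fringe_freq, pixel_size=px,
                           reference_phase=ref_phase)

    return CurvedScene(
        distorted=distorted,
        undistorted=undistorted,
        fringes=_fringes(phase),
        reference_fringes=_fringes(ref_phase),
        height=h,
        height_max=spec.height_max,
        c_field=c,
        footprint=footprint,
        scene_map=opmap,
        bruise_mask=bruise_mask,
        sound_mask=sound_mask,
    )
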