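"""Synthetic pulsatile-fundus-video generator with ground truth.

Renders short video clips that emulate the recording conditions of the
clinical setup — a bright disc background, curvilinear dark vessels
whose haemoglobin absorbance modulates sinusoidally with cardiac phase,
slow illumination drift, small inter-frame translational/rotational
jitter, and Gaussian sensor noise — together with the exact per-cluster
pulsation amplitudes and a binary pulsation mask, so that every pipeline
stage can be tested against known truth without clinical recordings.

The rendering equation per frame at time t:

    I(x, y, t) = bit_max * illum(t) * profile(x, y) * 10^(-A(x, y, t) / 68)

with absorbance ``A = baseline + (amp / 2) * w(phase(t) - offset)`` on
vessel support, where the waveform ``w`` has unit amplitude (peak-to-
trough 2) so that ``amp`` is exactly the per-pixel peak-to-trough
absorbance in map units.  Jitter is applied as the final geometric
transform; noise is added in intensity space and quantised to the
camera bit depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

from .stacks import BeatTimes, FrameStack

__all__ = ["Vessel", "SceneSpec", "GroundTruth", "generate", "preset_scenes"]

_DEFAULT_ONSETS = (0.0, 1.0, 2.0, 3.0)


@dataclass
class Vessel:
    """One curvilinear vessel: centreline polyline plus optical parameters.

    ``amplitude`` is the per-pixel peak-to-trough absorbance modulation in
    map units; ``second_harmonic`` adds a dicrotic-notch-like component.
    """

    points: tuple  # ((row, col), ...) centreline vertices, pixels
    width: float = 6.0  # pixels
    baseline: float = 18.0  # static absorbance, map units
    amplitude: float = 10.0  # peak-to-trough absorbance modulation, map units
    phase_offset: float = 0.0  # cardiac-phase delay of the waveform
    second_harmonic: float = 0.0  # relative weight of the 2nd harmonic
    feather: float = 1.0  # edge softening width, px; 0 = hard edge


@dataclass
class SceneSpec:
    """Full description of a synthetic recording."""

    height: int = 200
    width: int = 200
    fps: float = 25.0
    onsets: tuple = _DEFAULT_ONSETS
    background_level: float = 180.0  # disc brightness, intensity levels
    vignette: float = 0.25  # radial fall-off of the background profile
    vessels: tuple = ()
    drift_amplitude: float = 0.0  # fractional illumination modulation
    drift_period: float = 3.0  # seconds
    jitter_translation: float = 0.0  # max |dx|,|dy| per frame, pixels
    jitter_rotation: float = 0.0  # max |rotation| per frame, degrees
    noise_sd: float = 0.0  # sensor noise SD, intensity levels
    scale_factor: float = 68.0
    bit_max: int = 255
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneSpec":
        raw = json.loads(Path(path).read_text())
        raw["vessels"] = tuple(
            Vessel(**{**v, "points": tuple(map(tuple, v["points"]))})
            for v in raw.get("vessels", ())
        )
        raw["onsets"] = tuple(raw.get("onsets", _DEFAULT_ONSETS))
        return cls(**raw)


@dataclass
class GroundTruth:
    """Exact answers for a rendered scene.

    ``cluster_amplitude`` is the mean over each 5x5 cluster's pixels of
    the per-pixel peak-to-trough absorbance range — the quantity the
    pipeline estimates.  ``full_mask``/``cluster_mask`` flag pulsatile
    pixels/clusters (any modulated pixel).  ``transforms`` holds the
    per-frame applied jitter as (dx, dy, rotation_deg).
    """

    pixel_amplitude: np.ndarray
    cluster_amplitude: np.ndarray
    full_mask: np.ndarray
    cluster_mask: np.ndarray
    transforms: np.ndarray
    covered_clusters: np.ndarray = field(default=None)


def _segment_distance(rr, cc, p0, p1):
    """Distance from every pixel to the segment p0-p1 (row/col coords)."""
    d = np.array(p1, float) - np.array(p0, float)
    L2 = float(d @ d)
    if L2 == 0:
        return np.hypot(rr - p0[0], cc - p0[1])
    t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2, 0.0, 1.0)
    return np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))


def _vessel_weight(spec: SceneSpec, vessel: Vessel) -> np.ndarray:
    """Smooth vessel support: 1 on the core, linear 1-px feather at edges."""
    rr, cc = np.meshgrid(
        np.arange(spec.height, dtype=float),
        np.arange(spec.width, dtype=float),
        indexing="ij",
    )
    pts = vessel.points
    for r, c in pts:
        if not (0 <= r < spec.height and 0 <= c < spec.width):
            raise ValueError(f"vessel vertex ({r}, {c}) outside {spec.height}x{spec.width} frame")
    dist = np.full((spec.height, spec.width), np.inf)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        np.minimum(dist, _segment_distance(rr, cc, p0, p1), out=dist)
    if vessel.feather <= 0:
        return (dist <= vessel.width / 2).astype(float)
    return np.clip((vessel.width / 2 + vessel.feather - dist) / vessel.feather,
                   0.0, 1.0)


def _waveform_coeffs(vessel: Vessel) -> tuple[float, float]:
    """Per-harmonic sine weights of the unit-amplitude waveform.

    w(phi) = (sin(2 pi phi) + h2 sin(4 pi phi)) / peak, normalised so the
    peak-to-trough range of w is exactly 2.
    """
    h2 = vessel.second_harmonic
    if h2 == 0:
        return 1.0, 0.0
    phi = np.linspace(0, 1, 4096, endpoint=False)
    w = np.sin(2 * np.pi * phi) + h2 * np.sin(4 * np.pi * phi)
    half_range = (w.max() - w.min()) / 2
    return 1.0 / half_range, h2 / half_range


def _phase_of(t: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    k = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 2)
    return (t - onsets[k]) / (onsets[k + 1] - onsets[k])


def generate(spec: SceneSpec) -> tuple[FrameStack, BeatTimes, GroundTruth]:
    """Render a scene; same spec (and seed) always yields bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    onsets = np.asarray(spec.onsets, dtype=float)
    n_frames = int(np.floor((onsets[-1] - onsets[0]) * spec.fps))
    t = onsets[0] + np.arange(n_frames) / spec.fps
    phases = _phase_of(t, onsets)

    h, w = spec.height, spec.width
    baseline = np.zeros((h, w))
    # per-pixel harmonic coefficient fields of the periodic absorbance
    sin1 = np.zeros((h, w))
    cos1 = np.zeros((h, w))
    sin2 = np.zeros((h, w))
    cos2 = np.zeros((h, w))
    for vessel in spec.vessels:
        wt = _vessel_weight(spec, vessel)
        baseline += vessel.baseline * wt
        c1, c2 = _waveform_coeffs(vessel)
        half = vessel.amplitude / 2.0 * wt
        th1 = 2 * np.pi * vessel.phase_offset
        th2 = 4 * np.pi * vessel.phase_offset
        sin1 += half * c1 * np.cos(th1)
        cos1 += -half * c1 * np.sin(th1)
        sin2 += half * c2 * np.cos(th2)
        cos2 += -half * c2 * np.sin(th2)

    # exact per-pixel peak-to-trough of the composite periodic field
    grid = np.linspace(0, 1, 512, endpoint=False)
    lo = np.full((h, w), np.inf)
    hi = np.full((h, w), -np.inf)
    for g in grid:
        val = (
            sin1 * np.sin(2 * np.pi * g)
            + cos1 * np.cos(2 * np.pi * g)
            + sin2 * np.sin(4 * np.pi * g)
            + cos2 * np.cos(4 * np.pi * g)
        )
        np.minimum(lo, val, out=lo)
        np.maximum(hi, val, out=hi)
    pixel_amplitude = np.where(np.isfinite(hi), hi - lo, 0.0)
    pixel_amplitude[pixel_amplitude < 1e-12] = 0.0

    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    r2 = ((rr - (h - 1) / 2) / (h / 2)) ** 2 + ((cc - (w - 1) / 2) / (w / 2)) ** 2
    profile = 1.0 - spec.vignette * r2

    transforms = np.zeros((n_frames, 3))
    if spec.jitter_translation > 0 or spec.jitter_rotation > 0:
        transforms[:, 0] = rng.uniform(-spec.jitter_translation, spec.jitter_translation, n_frames)
        transforms[:, 1] = rng.uniform(-spec.jitter_translation, spec.jitter_translation, n_frames)
        transforms[:, 2] = rng.uniform(-spec.jitter_rotation, spec.jitter_rotation, n_frames)
        transforms[0] = 0.0  # reference frame stays put

    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    centre = np.array([(w - 1) / 2, (h - 1) / 2])
    for i, (ti, phi) in enumerate(zip(t, phases)):
        A = baseline + (
            sin1 * np.sin(2 * np.pi * phi)
            + cos1 * np.cos(2 * np.pi * phi)
            + sin2 * np.sin(4 * np.pi * phi)
            + cos2 * np.cos(4 * np.pi * phi)
        )
        illum = 1.0 + spec.drift_amplitude * np.sin(
            2 * np.pi * (ti - t[0]) / spec.drift_period
        )
        green = spec.bit_max * illum * profile * 10.0 ** (-A / spec.scale_factor)
        dx, dy, rot = transforms[i]
        if dx or dy or rot:
            tf = (
                AffineTransform(translation=-centre)
                + AffineTransform(rotation=np.deg2rad(rot))
                + AffineTransform(translation=centre + [dx, dy])
            )
            green = warp(green, tf.inverse, order=1, mode="edge", preserve_range=True)
        if spec.noise_sd > 0:
            green = green + rng.normal(0.0, spec.noise_sd, green.shape)
        g8 = np.clip(np.rint(green), 0, spec.bit_max).astype(np.uint8)
        # red/blue carry an attenuated copy so frames look plausibly fundus-like
        frames[i, :, :, 0] = np.clip(np.rint(green * 0.85), 0, spec.bit_max).astype(np.uint8)
        frames[i, :, :, 1] = g8
        frames[i, :, :, 2] = np.clip(np.rint(green * 0.35), 0, spec.bit_max).astype(np.uint8)

    s = 5
    nr, nc = h // s, w // s
    blocks = pixel_amplitude[: nr * s, : nc * s].reshape(nr, s, nc, s)
    cluster_amplitude = blocks.mean(axis=(1, 3))
    full_mask = (pixel_amplitude > 0).astype(np.uint8)
    cluster_mask = (blocks > 0).any(axis=(1, 3)).astype(np.uint8)
    covered = np.all(blocks == blocks[:, :1, :, :1], axis=(1, 3)) & (cluster_amplitude > 0)

    stack = FrameStack(frames=frames, fps=spec.fps, timestamps=t)
    truth = GroundTruth(
        pixel_amplitude=pixel_amplitude,
        cluster_amplitude=cluster_amplitude,
        full_mask=full_mask,
        cluster_mask=cluster_mask,
        transforms=transforms,
        covered_clusters=covered,
    )
    return stack, BeatTimes(onsets=onsets), truth


def _default_vessels(amplitude: float = 10.0) -> tuple[Vessel, ...]:
    """Two curvilinear vessels crossing a 200x200 disc."""
    arc1 = tuple(
        (float(r), float(100 + 35 * np.sin(np.pi * r / 180)))
        for r in range(10, 191, 12)
    )
    arc2 = tuple(
        (float(60 + 25 * np.sin(np.pi * c / 150)), float(c))
        for c in range(20, 181, 12)
    )
    return (
        Vessel(points=arc1, width=8.0, baseline=18.0, amplitude=amplitude,
               second_harmonic=0.3),
        Vessel(points=arc2, width=5.0, baseline=14.0, amplitude=amplitude * 0.6,
               phase_offset=0.1),
    )


def preset_scenes(seed: int = 0) -> dict[str, SceneSpec]:
    """Named study-condition presets.

    ``clean``     no nuisance terms — parameter-recovery baseline.
    ``noisy``     Gaussian sensor noise, SD 2 intensity levels.
    ``drift``     sinusoidal illumination drift giving a whole-frame
                  intensity SD inside the clinically observed 0.5-3.5 band.
    ``wobble``    translational/rotational jitter comparable (after
                  scaling to the 200-px frame) to the recorded movement range.
    ``separable`` pulsatile amplitudes >= 10 units on zero background, so
                  detection against the truth mask is perfectly separable.
    """
    base = dict(height=200, width=200, fps=25.0, onsets=_DEFAULT_ONSETS, seed=seed)
    return {
        "clean": SceneSpec(vessels=_default_vessels(10.0), **base),
        "noisy": SceneSpec(vessels=_default_vessels(10.0), noise_sd=2.0, **base),
        "drift": SceneSpec(
            vessels=_default_vessels(10.0), drift_amplitude=0.02, drift_period=3.0, **base
        ),
        "wobble": SceneSpec(
            vessels=_default_vessels(10.0),
            jitter_translation=6.0,
            jitter_rotation=1.0,
            **base,
        ),
        # hard-edged bars snapped to the 5-px cluster grid: every annotated
        # cluster is fully covered, so cluster amplitudes are >= 12 on the
        # mask and 0 off it — detection is perfectly separable
        "separable": SceneSpec(
            vessels=(
                Vessel(points=((57.0, 0.0), (57.0, 199.0)), width=15.0,
                       baseline=18.0, amplitude=12.0, feather=0.0),
                Vessel(points=((0.0, 132.0), (199.0, 132.0)), width=15.0,
                       baseline=14.0, amplitude=15.0, feather=0.0),
            ),
            **base,
        ),
    }
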