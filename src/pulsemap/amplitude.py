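"""Photo-plethysmographic amplitude mapping.

The signal model: transmitted green intensity relates to haemoglobin
optical path length through the Beer-Lambert law, so absorbance
``A = 68 * (-log10(I / I_max))`` is (up to the fixed calibration factor)
proportional to path length.  The image is tiled into non-overlapping
5x5-pixel clusters; each cluster's mean absorbance over time is
regressed on a cardiac-periodic harmonic basis plus a continuous
piecewise-linear drift term (knots at beat onsets) that soaks up slow
movement/illumination artefact.  The pulsation amplitude of a cluster is
the peak-to-trough range of the fitted periodic component — drift and
intercept excluded — reported in the same arbitrary units (nominally
microns of half path length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .stacks import BeatTimes, FrameStack, PhaseVector, compute_phase, extract_green

__all__ = [
    "beer_lambert_transform",
    "cluster_means",
    "harmonic_design",
    "fit_harmonic",
    "amplitude_from_fit",
    "amplitude_map",
    "illumination_index",
    "ClusterCube",
    "HarmonicFit",
    "AmplitudeMap",
    "IlluminationIndex",
    "PulsationMapper",
]

logger = logging.getLogger(__name__)

DEFAULT_SCALE_FACTOR = 68.0  # calibration constant: absorbance units ~ half path length (um)
DEFAULT_CLUSTER_SIZE = 5
DEFAULT_N_HARMONICS = 2
DEFAULT_PHASE_GRID = 1000


@dataclass
class ClusterCube:
    """Per-cluster mean absorbance over time.

    ``values`` has shape (n_rows, n_cols, n_frames) where the grid is the
    floor(H/5) x floor(W/5) tiling anchored at pixel (0, 0).
    """

    values: np.ndarray
    phase: PhaseVector = None
    cluster_size: int = DEFAULT_CLUSTER_SIZE

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


@dataclass
class HarmonicFit:
    """One cluster's harmonic-plus-spline regression fit.

    The cardiac-periodic component is
    ``c(phi) = sum_k a[k-1] cos(2 pi k phi) + b[k-1] sin(2 pi k phi)``,
    with period 1 in phase by construction.  Spline coefficients multiply
    the continuous piecewise-linear time basis (slope plus one hinge per
    interior beat onset).
    """

    intercept: float
    a: np.ndarray
    b: np.ndarray
    spline_coef: np.ndarray
    knots: np.ndarray
    residual_var: float
    n_harmonics: int

    def periodic(self, phi: np.ndarray) -> np.ndarray:
        """Evaluate the fitted cardiac-periodic component at phase ``phi``."""
        phi = np.asarray(phi, dtype=float)
        k = np.arange(1, self.n_harmonics + 1)
        ang = 2 * np.pi * np.multiply.outer(phi, k)
        return np.cos(ang) @ self.a + np.sin(ang) @ self.b

    def periodic_derivative(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        k = np.arange(1, self.n_harmonics + 1)
        ang = 2 * np.pi * np.multiply.outer(phi, k)
        return -np.sin(ang) @ (2 * np.pi * k * self.a) + np.cos(ang) @ (
            2 * np.pi * k * self.b
        )


@dataclass
class AmplitudeMap:
    """Per-cluster pulsation amplitude on the 5:1 downscaled grid."""

    amplitude: np.ndarray
    cluster_size: int = DEFAULT_CLUSTER_SIZE
    failed: np.ndarray = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


@dataclass
class IlluminationIndex:
    """Whole-frame green intensity summary; the SD indexes illumination drift."""

    mean_intensity: float
    sd_intensity: float


def beer_lambert_transform(
    green: np.ndarray | float,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    bit_max: int = 255,
) -> np.ndarray | float:
    """Map raw green intensity to absorbance units.

    Intensities are normalised by the bit-depth maximum so full
    transmittance maps to exactly 0; zeros are clamped to half the least
    count (``1 / (2 * bit_max)``) to keep the logarithm finite.  The fixed
    factor 68 converts decadic absorbance to the nominal half-path-length
    scale used throughout ("arbitrary units").
    """
    x = np.asarray(green, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    norm = np.clip(x / bit_max, 1.0 / (2 * bit_max), 1.0)
    out = scale_factor * (-np.log10(norm))
    if np.isscalar(green) or np.ndim(green) == 0:
        return float(out)
    return out


def cluster_means(
    transformed: np.ndarray,
    cluster_size: int = DEFAULT_CLUSTER_SIZE,
    phase: PhaseVector = None,
) -> ClusterCube:
    """Average transformed frames over a non-overlapping square tiling.

    ``transformed`` has shape (n_frames, H, W).  The tiling is anchored at
    pixel (0, 0); trailing rows/columns that do not fill a whole cluster
    are dropped, giving a floor(H/s) x floor(W/s) grid.
    """
    transformed = np.asarray(transformed, dtype=float)
    n, h, w = transformed.shape
    s = cluster_size
    if h < s or w < s:
        raise ValueError(f"frame {h}x{w} smaller than cluster size {s}")
    nr, nc = h // s, w // s
    trimmed = transformed[:, : nr * s, : nc * s]
    cube = trimmed.reshape(n, nr, s, nc, s).mean(axis=(2, 4))
    return ClusterCube(values=np.moveaxis(cube, 0, 2), phase=phase, cluster_size=s)


def harmonic_design(
    phase: np.ndarray,
    time: np.ndarray,
    beats: BeatTimes,
    n_harmonics: int = DEFAULT_N_HARMONICS,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the regression design matrix for the included frames.

    Columns: intercept; cos/sin pairs at harmonics 1..H of cardiac phase;
    then the drift basis — centred time and one hinge ``max(t - knot, 0)``
    per interior beat onset, together a continuous piecewise-linear
    function of absolute time with one slope per cardiac cycle.

    Returns ``(X, knots)``.
    """
    phase = np.asarray(phase, dtype=float)
    time = np.asarray(time, dtype=float)
    k = np.arange(1, n_harmonics + 1)
    ang = 2 * np.pi * np.multiply.outer(phase, k)
    knots = beats.onsets[1:-1]
    cols = [np.ones_like(phase)]
    for j in range(n_harmonics):
        cols.append(np.cos(ang[:, j]))
        cols.append(np.sin(ang[:, j]))
    cols.append(time - time.mean())
    for knot in knots:
        cols.append(np.maximum(time - knot, 0.0))
    return np.column_stack(cols), knots


def _unpack(coef: np.ndarray, knots: np.ndarray, n_harmonics: int, resid_var: float) -> HarmonicFit:
    h = n_harmonics
    return HarmonicFit(
        intercept=float(coef[0]),
        a=coef[1 : 1 + 2 * h : 2].copy(),
        b=coef[2 : 2 + 2 * h : 2].copy(),
        spline_coef=coef[1 + 2 * h :].copy(),
        knots=np.asarray(knots, dtype=float),
        residual_var=float(resid_var),
        n_harmonics=h,
    )


def fit_harmonic(
    series: np.ndarray,
    phase: PhaseVector,
    beats: BeatTimes,
    n_harmonics: int = DEFAULT_N_HARMONICS,
) -> HarmonicFit:
    """Least-squares harmonic regression of one cluster's time series.

    Only frames inside complete cardiac cycles enter the fit.  Raises on
    a rank-deficient design or when fewer than three cycles are covered.
    """
    y = np.asarray(series, dtype=float)
    inc = phase.included
    if np.unique(phase.cycle_index[inc]).size < 3:
        raise ValueError("need frames from >=3 complete cardiac cycles")
    X, knots = harmonic_design(phase.phase[inc], phase.time[inc], beats, n_harmonics)
    if X.shape[0] < X.shape[1]:
        raise ValueError(
            f"{X.shape[0]} observations cannot identify {X.shape[1]} coefficients"
        )
    coef, _, rank, _ = np.linalg.lstsq(X, y[inc], rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient harmonic design matrix")
    resid = y[inc] - X @ coef
    dof = max(X.shape[0] - X.shape[1], 1)
    return _unpack(coef, knots, n_harmonics, resid @ resid / dof)


def amplitude_from_fit(fit: HarmonicFit, phase_grid: int = DEFAULT_PHASE_GRID) -> float:
    """Peak-to-trough range of the fitted periodic component.

    Extrema are bracketed on a dense phase grid and refined at the sign
    changes of the analytic derivative, so the range is exact to root
    tolerance rather than grid resolution.
    """
    phi = np.linspace(0.0, 1.0, phase_grid, endpoint=False)
    c = fit.periodic(phi)
    if not np.any(np.abs(c) > 0):
        return 0.0
    d = fit.periodic_derivative(phi)
    candidates = [c.min(), c.max()]
    sign = np.sign(d)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    step = 1.0 / phase_grid
    for i in flips:
        root = brentq(fit.periodic_derivative, phi[i], phi[i] + step, xtol=1e-12)
        candidates.append(float(fit.periodic(root)))
    return float(max(candidates) - min(candidates))


def amplitude_map(
    cube: ClusterCube,
    beats: BeatTimes,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    phase_grid: int = DEFAULT_PHASE_GRID,
    max_failure_fraction: float = 0.10,
) -> AmplitudeMap:
    """Fit every cluster and extract its pulsation amplitude.

    All clusters share one design matrix (phase is a per-frame quantity),
    so the least-squares problem is solved for every cluster in a single
    call.  Clusters whose series are non-finite get amplitude 0 and a
    failure flag; more than ``max_failure_fraction`` failures aborts.
    """
    phase = cube.phase
    if phase is None:
        raise ValueError("cluster cube carries no phase information")
    inc = phase.included
    if np.unique(phase.cycle_index[inc]).size < 3:
        raise ValueError("need frames from >=3 complete cardiac cycles")
    nr, nc = cube.n_rows, cube.n_cols
    Y = cube.values.reshape(nr * nc, cube.n_frames)[:, inc].T
    X, _ = harmonic_design(phase.phase[inc], phase.time[inc], beats, n_harmonics)
    failed = ~np.all(np.isfinite(Y), axis=0)
    Yc = np.where(np.isfinite(Y), Y, 0.0)
    coef, _, rank, _ = np.linalg.lstsq(X, Yc, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient harmonic design matrix")

    # peak-to-trough of the periodic component on a dense phase grid
    h = n_harmonics
    phi = np.linspace(0.0, 1.0, phase_grid, endpoint=False)
    k = np.arange(1, h + 1)
    ang = 2 * np.pi * np.multiply.outer(phi, k)
    G = np.concatenate([np.cos(ang), np.sin(ang)], axis=1)  # (grid, 2H)
    harm = np.concatenate([coef[1 : 1 + 2 * h : 2], coef[2 : 2 + 2 * h : 2]])
    curves = G @ harm  # (grid, n_clusters)
    amp = curves.max(axis=0) - curves.min(axis=0)
    amp[failed] = 0.0

    n_failed = int(failed.sum())
    if n_failed:
        logger.warning("amplitude_map: %d/%d cluster fits failed", n_failed, nr * nc)
    if n_failed > max_failure_fraction * nr * nc:
        raise RuntimeError(
            f"{n_failed}/{nr * nc} cluster fits failed "
            f"(> {max_failure_fraction:.0%} tolerated)"
        )
    return AmplitudeMap(
        amplitude=amp.reshape(nr, nc),
        cluster_size=cube.cluster_size,
        failed=failed.reshape(nr, nc),
    )


def illumination_index(stack: FrameStack) -> IlluminationIndex:
    """Mean and sample SD of the whole-frame mean green intensity over time.

    The SD is the recording's illumination-variation index ("Illum sd").
    """
    means = extract_green(stack).astype(float).mean(axis=(1, 2))
    return IlluminationIndex(
        mean_intensity=float(means.mean()),
        sd_intensity=float(means.std(ddof=1)),
    )


class PulsationMapper(BaseEstimator):
    """Estimate a per-cluster pulsation-amplitude map from a frame stack.

    Transform-shaped estimator: ``fit(stack, beats)`` runs green-channel
    extraction, the Beer-Lambert absorbance transform, 5x5 clustering and
    per-cluster harmonic regression, leaving the results in fitted
    attributes.

    Parameters
    ----------
    n_harmonics : int, default 2
        Harmonics of the cardiac frequency in the periodic basis.  Two
        capture the systolic peak and dicrotic shoulder.
    cluster_size : int, default 5
        Square cluster edge in pixels.
    scale_factor : float, default 68
        Beer-Lambert calibration constant (absorbance units per decade).
    phase_grid : int, default 1000
        Phase-grid resolution for amplitude extraction.
    bit_max : int or None, default None
        Intensity full-scale; ``None`` uses the stack dtype's maximum.

    Attributes
    ----------
    amplitude_map_ : AmplitudeMap
    cube_ : ClusterCube
    phase_ : PhaseVector
    illumination_ : IlluminationIndex
    n_clusters_ : int
    n_failed_ : int
    """

    def __init__(
        self,
        n_harmonics: int = DEFAULT_N_HARMONICS,
        cluster_size: int = DEFAULT_CLUSTER_SIZE,
        scale_factor: float = DEFAULT_SCALE_FACTOR,
        phase_grid: int = DEFAULT_PHASE_GRID,
        bit_max: int | None = None,
    ):
        self.n_harmonics = n_harmonics
        self.cluster_size = cluster_size
        self.scale_factor = scale_factor
        self.phase_grid = phase_grid
        self.bit_max = bit_max

    def fit(self, stack: FrameStack, beats: BeatTimes) -> "PulsationMapper":
        if not 1 <= self.n_harmonics <= 4:
            raise ValueError("n_harmonics must be in 1..4")
        bit_max = self.bit_max if self.bit_max is not None else stack.bit_max
        phase = compute_phase(stack, beats)
        green = extract_green(stack)
        absorb = beer_lambert_transform(green, self.scale_factor, bit_max)
        cube = cluster_means(absorb, self.cluster_size, phase)
        self.amplitude_map_ = amplitude_map(
            cube, beats, n_harmonics=self.n_harmonics, phase_grid=self.phase_grid
        )
        self.cube_ = cube
        self.phase_ = phase
        self.illumination_ = illumination_index(stack)
        self.n_clusters_ = cube.n_rows * cube.n_cols
        self.n_failed_ = int(self.amplitude_map_.failed.sum())
        return self

    def transform(self, stack: FrameStack = None) -> np.ndarray:
        """Return the fitted amplitude grid (n_rows, n_cols)."""
        if not hasattr(self, "amplitude_map_"):
            raise RuntimeError("PulsationMapper is not fitted")
        return self.amplitude_map_.amplitude
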