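"""Affine frame alignment, movement index and common-region cropping.

Frames are registered to a reference frame by minimising the
mean-squared green-channel difference over a composite affine model
(translation, rotation, shear, isotropic scale), coarse-to-fine over an
image pyramid, with a phase-correlation translation initialiser.  Warped
pixels that fall outside the camera view carry an explicit validity
flag, so the subsequent crop to the commonly visible region is exact.

The recording's movement index ("Tot Movt") is the Pythagorean
combination of the largest horizontal and vertical translation spread
across frames: ``sqrt(max_dx**2 + max_dy**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, rescale, warp
from sklearn.base import BaseEstimator

from .stacks import FrameStack, extract_green

__all__ = [
    "AlignmentResult",
    "StackAligner",
    "align_stack",
    "displacement_index",
    "crop_common",
]


@dataclass
class AlignmentResult:
    """Aligned stack plus the recovered per-frame transforms.

    ``transforms`` columns: tx, ty (pixels, x = column / y = row),
    rotation (radians), shear (radians), scale.  The reference frame's
    row is the identity (0, 0, 0, 0, 1).
    """

    aligned: FrameStack
    transforms: np.ndarray
    reference_index: int
    max_dx: float
    max_dy: float
    crop_box: tuple[int, int, int, int]

    @property
    def displacement_index(self) -> float:
        return displacement_index(self.max_dx, self.max_dy)


def displacement_index(max_dx: float, max_dy: float) -> float:
    """Pythagorean movement index: sqrt(max_dx^2 + max_dy^2), pixels."""
    return float(np.hypot(max_dx, max_dy))


def _params_to_transform(p: np.ndarray, centre: np.ndarray) -> AffineTransform:
    """(tx, ty, rot, shear, log_scale) about the frame centre -> forward transform."""
    tx, ty, rot, shear, log_s = p
    return (
        AffineTransform(translation=-centre)
        + AffineTransform(rotation=rot, shear=shear, scale=np.exp(log_s))
        + AffineTransform(translation=centre + [tx, ty])
    )


def _mse(p, fixed, moving, centre, order=1):
    # cubic interpolation at the finest level: bilinear MSE has spurious
    # local minima at integer shifts that trap sub-pixel refinement
    tf = _params_to_transform(p, centre)
    warped = warp(moving, tf, order=order, mode="constant", cval=np.nan,
                  preserve_range=True)
    ok = np.isfinite(warped)
    if ok.sum() < 0.25 * ok.size:
        return np.inf
    d = warped[ok] - fixed[ok]
    return float(d @ d / ok.sum())


class StackAligner(BaseEstimator):
    """Affine-register every frame of a stack to a reference frame.

    ``fit`` recovers the transforms; ``transform`` applies them and
    returns the aligned stack with per-pixel validity flags.

    Parameters
    ----------
    reference_index : int, default 0
        Frame all others are matched to.
    pyramid : tuple of int, default (4, 2, 1)
        Coarse-to-fine downscale factors for the optimiser.
    model : {'affine', 'euclidean'}, default 'affine'
        'euclidean' freezes shear and scale (translation + rotation only).
    max_iter : int, default 120
        Powell iteration cap per pyramid level.

    Attributes
    ----------
    transforms_ : ndarray (n_frames, 5) — tx, ty, rot, shear, scale
    max_dx_, max_dy_ : float — largest pairwise translation spread
    result_ : AlignmentResult, set by :meth:`transform`
    """

    def __init__(self, reference_index: int = 0, pyramid: tuple = (4, 2, 1),
                 model: str = "affine", max_iter: int = 120):
        self.reference_index = reference_index
        self.pyramid = pyramid
        self.model = model
        self.max_iter = max_iter

    def fit(self, stack: FrameStack, y=None) -> "StackAligner":
        if not 0 <= self.reference_index < stack.n_frames:
            raise ValueError(f"reference_index {self.reference_index} out of range")
        if self.model not in ("affine", "euclidean"):
            raise ValueError("model must be 'affine' or 'euclidean'")
        green = extract_green(stack).astype(float)
        ref = green[self.reference_index]
        params = np.zeros((stack.n_frames, 5))
        for i in range(stack.n_frames):
            if i == self.reference_index:
                continue
            try:
                params[i] = self._register_pair(ref, green[i])
            except Exception as exc:  # noqa: BLE001 — name the failing frame
                raise RuntimeError(f"registration failed on frame {i}: {exc}") from exc
        self.transforms_ = np.column_stack(
            [params[:, :4], np.exp(params[:, 4])]
        )
        self.max_dx_ = float(np.ptp(params[:, 0]))
        self.max_dy_ = float(np.ptp(params[:, 1]))
        self.n_frames_ = stack.n_frames
        return self

    def _register_pair(self, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
        levels = sorted(set(int(f) for f in self.pyramid), reverse=True)
        p = np.zeros(5)
        # translation seed at the coarsest level via phase correlation
        f0 = int(levels[0])
        fx = rescale(fixed, 1 / f0, anti_aliasing=True) if f0 > 1 else fixed
        mv = rescale(moving, 1 / f0, anti_aliasing=True) if f0 > 1 else moving
        shift, _, _ = phase_cross_correlation(fx, mv, upsample_factor=10,
                                              normalization=None)
        p[0], p[1] = -shift[1] * f0, -shift[0] * f0
        free = slice(0, 5) if self.model == "affine" else slice(0, 3)
        for factor in levels:
            if factor > 1:
                fx = rescale(fixed, 1 / factor, anti_aliasing=True)
                mv = rescale(moving, 1 / factor, anti_aliasing=True)
            else:
                fx, mv = fixed, moving
            centre = np.array([(mv.shape[1] - 1) / 2, (mv.shape[0] - 1) / 2])
            scale = np.array([factor, factor, 1.0, 1.0, 1.0], dtype=float)
            order = 3 if factor == 1 else 1

            def objective(q, base=p.copy(), sc=scale, fixed_=fx, moving_=mv,
                          c=centre, o=order):
                full = base.copy()
                full[free] = q
                return _mse(full / sc, fixed_, moving_, c, order=o)

            res = minimize(objective, p[free], method="Powell",
                           options={"maxiter": self.max_iter, "xtol": 1e-4,
                                    "ftol": 1e-8})
            p[free] = res.x
        return p

    def transform(self, stack: FrameStack) -> AlignmentResult:
        if not hasattr(self, "transforms_"):
            raise RuntimeError("StackAligner is not fitted")
        n, h, w = stack.n_frames, stack.height, stack.width
        centre = np.array([(w - 1) / 2, (h - 1) / 2])
        aligned = np.empty((n, h, w, 3), dtype=float)
        valid = np.empty((n, h, w), dtype=bool)
        for i in range(n):
            tx, ty, rot, shear, sc = self.transforms_[i]
            if i == self.reference_index or not np.any(
                [tx, ty, rot, shear, sc - 1.0]
            ):
                aligned[i] = stack.frames[i]
                valid[i] = True
                continue
            tf = _params_to_transform([tx, ty, rot, shear, np.log(sc)], centre)
            # inverse warp: moving -> reference geometry
            for ch in range(3):
                aligned[i, :, :, ch] = warp(
                    stack.frames[i, :, :, ch].astype(float), tf,
                    order=1, mode="constant", cval=0.0, preserve_range=True,
                )
            ones = warp(np.ones((h, w)), tf, order=1, mode="constant", cval=0.0)
            valid[i] = ones > 0.999
        out = FrameStack(frames=aligned, fps=stack.fps,
                         timestamps=stack.timestamps, valid=valid)
        crop = _largest_valid_box(valid.all(axis=0))
        self.result_ = AlignmentResult(
            aligned=out,
            transforms=self.transforms_.copy(),
            reference_index=self.reference_index,
            max_dx=self.max_dx_,
            max_dy=self.max_dy_,
            crop_box=crop,
        )
        return self.result_

    def fit_transform(self, stack: FrameStack, y=None) -> AlignmentResult:
        return self.fit(stack).transform(stack)


def align_stack(stack: FrameStack, reference_index: int = 0,
                model: str = "affine") -> AlignmentResult:
    """Align all frames to ``stack.frames[reference_index]``; see StackAligner."""
    return StackAligner(reference_index=reference_index, model=model).fit_transform(stack)


def _largest_valid_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Largest axis-aligned all-True rectangle (row0, col0, row1, col1), half-open.

    Histogram-stack algorithm, O(H*W)."""
    h, w = mask.shape
    if not mask.any():
        raise ValueError("no pixel is valid in every frame; cannot crop")
    heights = np.zeros(w, dtype=int)
    best = (0, (0, 0, 0, 0))
    for r in range(h):
        heights = np.where(mask[r], heights + 1, 0)
        stack_: list[int] = []
        j = 0
        ext = np.append(heights, 0)
        while j <= w:
            if not stack_ or ext[j] >= ext[stack_[-1]]:
                stack_.append(j)
                j += 1
            else:
                top = stack_.pop()
                left = stack_[-1] + 1 if stack_ else 0
                area = ext[top] * (j - left)
                if area > best[0]:
                    best = (area, (r + 1 - ext[top], left, r + 1, j))
    return tuple(int(v) for v in best[1])


def crop_common(result: AlignmentResult) -> FrameStack:
    """Crop the aligned stack to the largest rectangle valid in every frame."""
    r0, c0, r1, c1 = result.crop_box
    aligned = result.aligned
    frames = aligned.frames[:, r0:r1, c0:c1, :]
    return FrameStack(frames=frames, fps=aligned.fps, timestamps=aligned.timestamps)
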