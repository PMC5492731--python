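"""Template matching: raw and normalized cross-correlation with rotation.

Raw cross-correlation C(i,j) = sum_{x,y} t(x,y) * p(x+i, y+j) is sensitive
to intensity changes, so the production matcher uses the normalized
cross-correlation

    R(i,j) = sum[(t - tbar)(p - pbar_ij)] /
             ( sqrt(sum (t - tbar)^2) * sqrt(sum (p - pbar_ij)^2) )

where tbar is the template mean (computed once) and pbar_ij the mean of the
image window under the template at placement (i,j).  R lies in [-1, 1] and
is invariant to positive affine intensity maps of either operand.  Objects
in arbitrary pose are handled by rotating the template over a fixed angle
grid and taking the global best score.

Placements are "valid" only (template fully inside the image), which keeps
the window statistics well defined; hens truncated at the frame edge are
covered by the detector's colored-pixel fallback.

Numerics: small images (<= _DIRECT_LIMIT pixels) use exact direct windowed
sums; camera-size frames use FFT convolution for the numerator and
integral-image window sums for the denominator (the classic fast-NCC
factorization), with windows of (near-)zero variance scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.signal import fftconvolve

from henmon.frame_io import BinaryMask
from henmon.templates import Template

__all__ = [
    "MatchResult",
    "cross_correlation",
    "normalized_cross_correlation",
    "match_template",
]

#: image sizes up to this many pixels use the exact direct path
_DIRECT_LIMIT = 128 * 128


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a rotation-search template match.

    ``location`` is the (row, col) of the top-left corner of the template
    footprint at the best placement; ``angle`` the rotation (degrees) at
    which the best score occurred.
    """

    found: bool
    score: float
    location: tuple[int, int]
    angle: float


def _check_dims(image: np.ndarray, template: np.ndarray) -> None:
    if image.ndim != 2 or template.ndim != 2:
        raise ValueError("image and template must be 2-D")
    if template.shape[0] > image.shape[0] or template.shape[1] > image.shape[1]:
        raise ValueError(
            f"template {template.shape} does not fit image {image.shape}"
        )


def cross_correlation(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Raw cross-correlation score surface over all valid placements.

    C(i,j) sums the template-weighted image values under the full template
    footprint; the output has shape (H - u + 1, W - v + 1) for an H x W
    image and u x v template.  Integer inputs yield an exact integer
    surface.
    """
    image = np.asarray(image)
    template = np.asarray(template)
    _check_dims(image, template)
    integer_inputs = np.issubdtype(image.dtype, np.integer) and np.issubdtype(
        template.dtype, np.integer
    )
    img = image.astype(np.float64)
    tpl = template.astype(np.float64)
    if img.size <= _DIRECT_LIMIT:
        windows = sliding_window_view(img, tpl.shape)
        surface = np.einsum("ijkl,kl->ij", windows, tpl)
    else:
        surface = fftconvolve(img, tpl[::-1, ::-1], mode="valid")
    if integer_inputs:
        surface = np.rint(surface)
        return surface.astype(np.int64)
    return surface


def _window_sums(img: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window sum and sum-of-squares via zero-padded integral images."""
    u, v = shape
    pad = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=pad[1:, 1:])
    s = pad[u:, v:] - pad[:-u, v:] - pad[u:, :-v] + pad[:-u, :-v]
    pad2 = np.zeros_like(pad)
    np.cumsum(np.cumsum(img * img, axis=0), axis=1, out=pad2[1:, 1:])
    s2 = pad2[u:, v:] - pad2[:-u, v:] - pad2[u:, :-v] + pad2[:-u, :-v]
    return s, s2


def normalized_cross_correlation(
    image: np.ndarray, template: np.ndarray
) -> np.ndarray:
    """Normalized cross-correlation surface R over all valid placements.

    |R| <= 1 everywhere; windows where the image patch is (numerically)
    constant score 0 by convention.  A constant template has an identically
    zero denominator and is rejected.
    """
    image = np.asarray(image, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    _check_dims(image, template)
    tz = template - template.mean()
    den_t = float(np.sqrt((tz * tz).sum()))
    if den_t == 0.0:
        raise ValueError("constant template: NCC denominator is identically zero")

    n = template.size
    if image.size <= _DIRECT_LIMIT:
        windows = sliding_window_view(image, template.shape)
        num = np.einsum("ijkl,kl->ij", windows, tz)
        win_sum = windows.sum(axis=(2, 3))
        win_sumsq = np.einsum("ijkl,ijkl->ij", windows, windows)
    else:
        num = fftconvolve(image, tz[::-1, ::-1], mode="valid")
        win_sum, win_sumsq = _window_sums(image, template.shape)

    den_p_sq = win_sumsq - win_sum * win_sum / n
    # guard against cancellation noise on (near-)constant windows
    tol = 1e-10 * np.maximum(win_sumsq, 1.0)
    flat = den_p_sq <= tol
    den_p = np.sqrt(np.maximum(den_p_sq, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / (den_t * den_p)
    r[flat] = 0.0
    return np.clip(r, -1.0, 1.0)


def rotate_template_mask(mask: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a binary template mask and crop to its tight bounding box."""
    if angle % 360 == 0:
        return np.asarray(mask, dtype=np.uint8)
    rotated = ndimage.rotate(
        np.asarray(mask, dtype=np.uint8), angle, reshape=True, order=0, prefilter=False
    )
    rows = np.any(rotated, axis=1)
    cols = np.any(rotated, axis=0)
    if not rows.any():
        return np.zeros((1, 1), dtype=np.uint8)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return rotated[r0 : r1 + 1, c0 : c1 + 1]


def match_template(
    mask: BinaryMask,
    template: Template,
    threshold: float = 0.5,
    angles: Sequence[float] | None = None,
) -> MatchResult:
    """Best NCC match of a rotating template over a binary foreground mask.

    Evaluates the NCC surface for each rotation of the template (binary
    values treated as 0/1 intensities), takes the global maximum over
    angles and placements, and accepts when it reaches ``threshold``.
    Ties are broken by the lowest angle, then the lowest (row, col).
    """
    if angles is None:
        angles = template.default_angles
    angles = list(angles)
    if not angles:
        raise ValueError("angle list must not be empty")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    img = mask.pixels.astype(np.float64)
    best_score = -np.inf
    best_loc = (0, 0)
    best_angle = angles[0]
    for angle in angles:
        tpl = rotate_template_mask(template.mask.pixels, angle)
        if tpl.shape[0] > img.shape[0] or tpl.shape[1] > img.shape[1]:
            raise ValueError(
                f"rotated template {tpl.shape} does not fit mask {img.shape}"
            )
        if tpl.min() == tpl.max():  # degenerate rotation (e.g. 1x1 crop)
            continue
        surface = normalized_cross_correlation(img, tpl.astype(np.float64))
        idx = np.unravel_index(int(np.argmax(surface)), surface.shape)
        score = float(surface[idx])
        if score > best_score:
            best_score = score
            best_loc = (int(idx[0]), int(idx[1]))
            best_angle = float(angle)
    if not np.isfinite(best_score):
        best_score = 0.0
    return MatchResult(
        found=best_score >= threshold,
        score=best_score,
        location=best_loc,
        angle=best_angle,
    )
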