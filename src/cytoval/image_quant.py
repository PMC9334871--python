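"""Semi-automated immunofluorescence quantification.

The procedure mirrors a common two-channel protocol: threshold the
structural-marker channel (e.g. a neuronal marker) with Li's
minimum-cross-entropy method, take the thresholded area as the selection,
and measure the mean gray value of the target channel inside it.  In batch
mode the threshold can either be recomputed per image or derived once from
a reference image (or the pooled histogram) and held constant.

Li's method picks the threshold t minimizing the cross entropy between the
image and its binary reconstruction,

    η(t) = − S₁(t)·ln μ₁(t) − S₂(t)·ln μ₂(t)

where μ₁/μ₂ and S₁/S₂ are the means and sums of the pixels at or below /
above t.  The implementation uses the standard fixed-point iteration
t ← (μ₁ − μ₂) / (ln μ₁ − ln μ₂), which converges to a minimum of η.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateDataError, SpecError
from .synthetic import TwoChannelImage

_EPS = 1e-12


def li_cross_entropy(image: np.ndarray, threshold: float) -> float:
    """Li's cross-entropy criterion for one candidate threshold."""
    x = np.asarray(image, dtype=float).ravel()
    lo = x[x <= threshold]
    hi = x[x > threshold]
    total = 0.0
    for part in (lo, hi):
        if part.size:
            mu = part.mean()
            if mu > 0:
                total -= part.sum() * math.log(mu)
    return total


def li_threshold(image: np.ndarray, tol: float = 0.5, max_iter: int = 200) -> float:
    """Li minimum-cross-entropy threshold via the iterative scheme.

    Iterates from the image mean until the update is below ``tol``
    (intensity units).  Raises for a constant image, whose histogram admits
    no threshold.
    """
    x = np.asarray(image, dtype=float).ravel()
    if x.size == 0:
        raise SpecError("empty image")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant image: degenerate histogram")
    # the criterion needs positive class means; shift a zero-based image
    shift = 0.0
    if x.min() <= 0:
        shift = -x.min() + _EPS
        x = x + shift
    t = float(x.mean())
    for _ in range(max_iter):
        lo = x[x <= t]
        hi = x[x > t]
        if lo.size == 0 or hi.size == 0:
            break
        m1, m2 = float(lo.mean()), float(hi.mean())
        if m1 <= 0:
            m1 = _EPS
        t_new = (m1 - m2) / (math.log(m1) - math.log(m2))
        if abs(t_new - t) <= tol:
            t = t_new
            break
        t = t_new
    return float(t - shift)


def li_threshold_exhaustive(image: np.ndarray) -> float:
    """Brute-force scan of all candidate thresholds (oracle path).

    Evaluates the cross-entropy criterion midway between every pair of
    adjacent distinct intensities and returns the argmin.
    """
    x = np.asarray(image, dtype=float).ravel()
    vals = np.unique(x)
    if vals.size < 2:
        raise DegenerateDataError("constant image: degenerate histogram")
    shift = 0.0
    if vals[0] <= 0:
        shift = -vals[0] + _EPS
        x = x + shift
        vals = vals + shift
    candidates = (vals[:-1] + vals[1:]) / 2.0
    best_t, best_val = candidates[0], math.inf
    for t in candidates:
        v = li_cross_entropy(x, t)
        if v < best_val:
            best_val, best_t = v, t
    return float(best_t - shift)


@dataclass(frozen=True)
class ICCQuantResult:
    """Threshold, marker mask size, and target mean gray inside the mask."""

    threshold: float
    mask_pixels: int
    mask_fraction: float
    mean_gray: float


def quantify_icc(
    image: TwoChannelImage, threshold: float | None = None
) -> ICCQuantResult:
    """Mean gray value of the target channel inside the marker mask.

    The mask is ``marker >= threshold`` (inclusive, no morphological
    cleanup); when no threshold is given Li's method is applied to the
    marker channel.  An empty mask is an error, not a zero.
    """
    t = li_threshold(image.marker) if threshold is None else float(threshold)
    mask = image.marker >= t
    n = int(mask.sum())
    if n == 0:
        raise DegenerateDataError("no marker-positive area above threshold")
    return ICCQuantResult(
        threshold=t,
        mask_pixels=n,
        mask_fraction=n / mask.size,
        mean_gray=float(image.target[mask].mean()),
    )


ThresholdPolicy = Literal["per_image", "constant_from_reference"]


def batch_quantify(
    images: Sequence[TwoChannelImage],
    policy: ThresholdPolicy = "constant_from_reference",
    reference_index: int | None = 0,
) -> list[ICCQuantResult]:
    """Quantify a batch under a per-image or constant-threshold policy.

    Under the constant policy the Li threshold is computed once — on the
    designated reference image, or on the pooled marker histogram when
    ``reference_index`` is None — and applied to every image.
    """
    if not images:
        raise SpecError("need at least one image")
    if policy == "per_image":
        return [quantify_icc(img) for img in images]
    if policy != "constant_from_reference":
        raise SpecError(f"unknown threshold policy {policy!r}")
    if reference_index is None:
        pooled = np.concatenate([img.marker.ravel() for img in images])
        t = li_threshold(pooled)
    else:
        t = li_threshold(images[reference_index].marker)
    return [quantify_icc(img, threshold=t) for img in images]
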