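"""Voxel-wise lower-distribution probability index and biopsy targets.

For a fitted double-Gaussian model, every ROI voxel with ADC value x is
scored with the index

    I(x) = [ ∫_x^∞ pdf_L − ∫_0^x pdf_H ] / [ ∫_x^∞ pdf_L + ∫_0^x pdf_H ]

where pdf_L and pdf_H are the (untruncated) Gaussian densities of the
lower and higher components. I ranges from −1 to 1; 1 means the voxel
is certainly represented by the lower distribution. Note the mixture
weight f does not enter the index. The integrals are evaluated in
closed form via the Gaussian CDF; the lower bound 0 of the pdf_H
integral is honored exactly (no truncation or renormalization).

A ``weighted`` variant multiplying each tail mass by its component
weight is available for exploration and is off by default; all shipped
results use the unweighted form.

Biopsy targets are 5 mm × 5 mm × 5 mm cubes chosen greedily on the
probability map: the admissible cube maximizing the mean index (the
low-ADC-distribution target) and the one minimizing it (the high-ADC
target), repeated per pair with cubes kept disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm

from .exceptions import NumericalError, ValidationError
from .mixture import DoubleGaussianFit
from .segmentation import EnhancementMask
from .volumes import AdcVolume

log = logging.getLogger(__name__)

TARGET_EDGE_MM = 5.0
_DENOM_FLOOR = 1e-300


def component_pdf(x, mu: float, sigma: float):
    """Gaussian probability density N(mu, sigma) evaluated at x."""
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    return norm.pdf(np.asarray(x, dtype=float), mu, sigma)


def probability_index(x, fit: DoubleGaussianFit, weighted: bool = False):
    """Lower-distribution probability index I(x) ∈ [−1, 1].

    Scalar in, scalar out; array in, array out. Requires x ≥ 0. Where
    both tail masses underflow, the sign-consistent limit ±1 is
    returned with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValidationError("ADC values must be non-negative")
    upper_L = norm.sf(x, fit.mu_L, fit.sigma_L)  # ∫_x^∞ pdf_L
    lower_H = norm.cdf(x, fit.mu_H, fit.sigma_H) - norm.cdf(0.0, fit.mu_H, fit.sigma_H)  # ∫_0^x pdf_H
    lower_H = np.maximum(lower_H, 0.0)
    if weighted:
        upper_L = fit.f * upper_L
        lower_H = (1.0 - fit.f) * lower_H
    num = upper_L - lower_H
    den = upper_L + lower_H
    tiny = den < _DENOM_FLOOR
    if np.any(tiny):
        log.warning("probability index denominator underflow at %d voxel(s); returning limit value", int(np.sum(tiny)))
        # decide the dominant tail in log space
        log_L = norm.logsf(np.where(tiny, x, fit.mu_L), fit.mu_L, fit.sigma_L)
        log_H = norm.logcdf(np.where(tiny, x, fit.mu_H), fit.mu_H, fit.sigma_H)
        limit = np.where(log_L > log_H, 1.0, -1.0)
        out = np.where(tiny, limit, np.divide(num, np.where(tiny, 1.0, den)))
    else:
        out = num / den
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ProbabilityMap:
    """Per-voxel index in [−1, 1] inside the ROI; NaN marks undefined voxels."""

    values: np.ndarray
    roi: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    fit: DoubleGaussianFit
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.values.shape != self.roi.shape:
            raise ValidationError("probability map and ROI shapes differ")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])


@dataclass
class BiopsyTarget:
    """A cubic biopsy target on the probability map."""

    center_voxel: tuple[int, int, int]
    center_mm: tuple[float, float, float]
    edge_mm: float
    mean_index: float
    label: str  # "low-ADC" (lower-distribution) or "high-ADC"


def make_probability_map(
    adc: AdcVolume, roi: EnhancementMask | np.ndarray, fit: DoubleGaussianFit,
    weighted: bool = False,
) -> ProbabilityMap:
    """Evaluate the probability index at every ROI voxel; NaN elsewhere."""
    mask = roi.mask if isinstance(roi, EnhancementMask) else np.asarray(roi, dtype=bool)
    if mask.shape != adc.shape:
        raise ValidationError("ROI shape does not match ADC volume")
    values = np.full(adc.shape, np.nan)
    inside = np.clip(adc.values[mask], 0.0, None)
    values[mask] = probability_index(inside, fit, weighted=weighted)
    return ProbabilityMap(
        values=values, roi=mask, voxel_size_mm=adc.voxel_size_mm, fit=fit, affine=adc.affine
    )


def _cube_edges_voxels(voxel_size_mm, edge_mm: float) -> tuple[int, int, int]:
    return tuple(max(1, int(round(edge_mm / s))) for s in voxel_size_mm)


def select_targets(
    pmap: ProbabilityMap,
    exclusion_mask: np.ndarray | None = None,
    n_pairs: int = 1,
    edge_mm: float = TARGET_EDGE_MM,
) -> list[BiopsyTarget]:
    """Greedy selection of high/low-ADC biopsy target pairs.

    Each pair is the admissible cube with maximal mean index (low-ADC
    target: high probability of the lower distribution) and the one
    with minimal mean index (high-ADC target). Admissible cubes lie
    entirely inside the ROI, avoid the exclusion mask, and are disjoint
    from previously selected cubes. Ties break toward the
    lexicographically smallest cube origin.
    """
    roi = pmap.roi
    edges = _cube_edges_voxels(pmap.voxel_size_mm, edge_mm)
    if any(e > s for e, s in zip(edges, roi.shape)):
        raise ValidationError("ROI too small for 5 mm target")
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != roi.shape:
            raise ValidationError("exclusion mask shape does not match map")

    admissible_src = roi & ~(exclusion_mask if exclusion_mask is not None else False)
    filled = np.where(np.isnan(pmap.values), 0.0, pmap.values)
    cube_n = int(np.prod(edges))

    mean_win = sliding_window_view(filled, edges).reshape(*[s - e + 1 for s, e in zip(roi.shape, edges)], cube_n).mean(axis=-1)
    used = np.zeros_like(roi)

    def admissible_origins() -> np.ndarray:
        ok_src = admissible_src & ~used
        win = sliding_window_view(ok_src, edges).reshape(mean_win.shape + (cube_n,))
        return win.all(axis=-1)

    def take(origin: tuple[int, int, int], label: str) -> BiopsyTarget:
        sl = tuple(slice(o, o + e) for o, e in zip(origin, edges))
        used[sl] = True
        center_v = tuple(int(o + (e - 1) // 2) for o, e in zip(origin, edges))
        hom = np.array([*[o + (e - 1) / 2.0 for o, e in zip(origin, edges)], 1.0])
        center_mm = tuple(float(c) for c in (pmap.affine @ hom)[:3])
        return BiopsyTarget(
            center_voxel=center_v,
            center_mm=center_mm,
            edge_mm=edge_mm,
            mean_index=float(mean_win[origin]),
            label=label,
        )

    targets: list[BiopsyTarget] = []
    for _ in range(n_pairs):
        ok = admissible_origins()
        if not ok.any():
            raise ValidationError("ROI too small for 5 mm target")
        vals = np.where(ok, mean_win, -np.inf)
        best = np.unravel_index(int(np.argmax(vals)), vals.shape)  # first max is lexicographic
        targets.append(take(tuple(int(i) for i in best), "low-ADC"))

        ok = admissible_origins()
        if not ok.any():
            raise ValidationError("ROI too small for 5 mm target")
        vals = np.where(ok, mean_win, np.inf)
        worst = np.unravel_index(int(np.argmin(vals)), vals.shape)
        targets.append(take(tuple(int(i) for i in worst), "high-ADC"))
    return targets
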