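"""Suitability-scaled abundance: density maps, totals and density targets.

The ensemble suitability map is converted to a per-cell density (animals
km^-2) through a chosen suitability-to-density shape, then rescaled so
that the area-weighted mean density over modelled-present cells (those at
or above the presence threshold) equals the debiased mean density from
the point process. Totals follow by summing density times cell area, with
confidence bounds obtained by recalibrating at the density CI endpoints
(the total is linear in the mean density at fixed suitability).

Three mapping shapes are supported:

* ``quadratic_unimodal`` — d(s) proportional to s(1-s): density peaks at
  intermediate suitability and declines toward the extremes.
* ``proportional`` — d(s) proportional to s.
* ``quadratic_monotone`` — d(s) proportional to s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DensityMap", "AbundanceSummary", "suitability_to_density", "total_population", "area_beyond_target"]

_SHAPES = {
    "quadratic_unimodal": lambda s: s * (1.0 - s),
    "proportional": lambda s: s,
    "quadratic_monotone": lambda s: s * s,
}


@dataclass
class DensityMap:
    """Per-cell expected density (animals km^-2) with its calibration record."""

    density: np.ndarray
    cell_area: float
    present_mask: np.ndarray
    calibration: dict = field(default_factory=dict)


@dataclass
class AbundanceSummary:
    total: float
    ci: tuple
    area_beyond_target: float = float("nan")
    fraction_beyond_target: float = float("nan")


def suitability_to_density(suitability, lambda_hat, mapping_kind="quadratic_unimodal", threshold=0.0, cell_area=1.0, lambda_ci=None):
    """Calibrated density map from a suitability map.

    Cells below the presence ``threshold`` get density 0; over the
    remaining cells the scale factor is chosen so their area-weighted mean
    density equals ``lambda_hat`` exactly.
    """
    s = np.asarray(suitability, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    if lambda_hat <= 0:
        raise ValueError("lambda_hat must be positive")
    if mapping_kind not in _SHAPES:
        raise KeyError(f"unknown mapping_kind {mapping_kind!r}; choose from {sorted(_SHAPES)}")
    present = s >= threshold
    if not present.any():
        raise ValueError("no cell at or above the presence threshold")
    g = _SHAPES[mapping_kind](s)
    mean_g = g[present].mean()
    if mean_g <= 0:
        raise ValueError("degenerate suitability map: zero mean shape value over present cells")
    density = np.where(present, lambda_hat * g / mean_g, 0.0)
    cal = {
        "lambda_hat": float(lambda_hat),
        "lambda_ci": tuple(lambda_ci) if lambda_ci is not None else None,
        "mapping_kind": mapping_kind,
        "mapping_params": {"threshold": float(threshold), "scale": float(lambda_hat / mean_g)},
    }
    return DensityMap(density=density, cell_area=float(cell_area), present_mask=present, calibration=cal)


def total_population(dmap: DensityMap, lambda_ci=None):
    """Total abundance (density times area summed) with CI by lambda rescaling."""
    total = float(dmap.density.sum() * dmap.cell_area)
    ci = lambda_ci if lambda_ci is not None else dmap.calibration.get("lambda_ci")
    lam = dmap.calibration.get("lambda_hat")
    if ci is not None and lam:
        lo, hi = ci
        ci = (total * lo / lam, total * hi / lam)
    else:
        ci = (total, total)
    return AbundanceSummary(total=total, ci=ci)


def area_beyond_target(dmap: DensityMap, target_per_ha=0.7):
    """Area (km^2) and fraction of modelled-present cells above the density cap.

    ``target_per_ha`` animals ha^-1 converts to 100x that per km^2.
    """
    if target_per_ha <= 0:
        raise ValueError("target must be positive")
    target_km2 = target_per_ha * 100.0
    beyond = dmap.density > target_km2
    area = float(beyond.sum() * dmap.cell_area)
    n_present = int(dmap.present_mask.sum())
    fraction = float(beyond.sum() / n_present) if n_present else 0.0
    return area, fraction
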