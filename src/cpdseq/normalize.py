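"""Fraction of CPDs remaining, anchored to a bulk gel measurement.

The core quantity everywhere downstream is

    fraction remaining = scale * sum_t / sum_0,

a ratio of aggregate counts (never a mean of per-site ratios: per-site 0 h
counts are mostly 0 or 1 at realistic depth). The scale is chosen so that
the genome-wide ratio equals the bulk fraction of unrepaired lesions
measured by alkaline-gel electrophoresis, which removes the arbitrary
library-depth difference between the two timepoints:

    scale = gel_fraction * T0 / Tt

with T0, Tt the genome-wide filtered lesion totals at 0 h and t h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, LesionMap


@dataclass(frozen=True)
class NormalizationFactor:
    """Depth normalization anchored to the bulk gel fraction remaining."""

    scale: float
    gel_fraction: float
    total_0h: int
    total_t: int

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise DataError(f"normalization scale must be > 0, got {self.scale}")


IDENTITY_NORM = NormalizationFactor(scale=1.0, gel_fraction=1.0, total_0h=1, total_t=1)


def make_normalization(
    lesions_0h: LesionMap, lesions_t: LesionMap, gel_fraction: float | None = None
) -> NormalizationFactor:
    """Build the per-condition normalization from two filtered lesion maps.

    With ``gel_fraction`` omitted, the degenerate ``G = 1`` mode is used
    (pure depth matching); downstream outputs record which mode applied.
    """
    g = 1.0 if gel_fraction is None else float(gel_fraction)
    if not 0 < g <= 1:
        raise DataError(f"gel_fraction must be in (0, 1], got {g}")
    t0 = lesions_0h.total()
    tt = lesions_t.total()
    if t0 == 0 or tt == 0:
        raise DataError("empty lesion map: cannot normalize")
    return NormalizationFactor(scale=g * t0 / tt, gel_fraction=g, total_0h=t0, total_t=tt)


def fraction_remaining(sum_t, sum_0, norm: NormalizationFactor):
    """Normalized fraction of lesions remaining for an aggregated position set.

    Accepts scalars or arrays. Where ``sum_0 == 0`` the fraction is undefined
    and returned as NaN (never 0, never inf); negative sums raise. Fractions
    above 1 are legitimate sampling noise and are not clipped.
    """
    t = np.asarray(sum_t, dtype=float)
    z = np.asarray(sum_0, dtype=float)
    if (t < 0).any() or (z < 0).any():
        raise DataError("negative lesion sums")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(z > 0, norm.scale * t / np.where(z > 0, z, 1.0), np.nan)
    if frac.ndim == 0:
        return float(frac)
    return frac
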