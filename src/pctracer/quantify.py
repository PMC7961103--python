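"""Tracer-incorporation statistics from images and shotgun intensity tables.

Labeled/unlabeled pixel ratios over a region, regional fold changes,
remodeling-product abundances relative to the administered dose at t=0,
and two-sample group comparison by the classical pooled-variance Student's
t-test (Welch's variant available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .processing import IonImage, RegionMask

__all__ = [
    "IncorporationResult",
    "incorporation_ratio",
    "region_fold_change",
    "remodeling_abundances",
    "group_compare",
]


@dataclass(frozen=True)
class IncorporationResult:
    """Mean +- SD of a pixelwise labeled/unlabeled intensity ratio."""

    ratio_mean: float
    ratio_sd: float
    n: int
    labeled_name: str = ""
    reference_name: str = ""

    @property
    def sem(self) -> float:
        return self.ratio_sd / np.sqrt(self.n) if self.n > 0 else float("nan")


def incorporation_ratio(
    labeled: IonImage,
    unlabeled: IonImage,
    mask: RegionMask | None = None,
    labeled_name: str = "",
    reference_name: str = "",
) -> IncorporationResult:
    """Pixelwise labeled/unlabeled ratio statistics over a region.

    Pixels where either image is missing or the denominator is zero are
    excluded (not treated as zero).  SD is the sample (n-1) standard
    deviation; it is 0 when only one valid pixel remains.
    """
    if labeled.values.shape != unlabeled.values.shape:
        raise ValueError("image shapes differ")
    sel = np.ones(labeled.values.shape, dtype=bool)
    if mask is not None:
        mask.require_shape(labeled.values.shape)
        sel = mask.values
    num = labeled.values
    den = unlabeled.values
    valid = sel & np.isfinite(num) & np.isfinite(den) & (den != 0)
    if not valid.any():
        raise ValueError("no valid pixels with nonzero denominator in the region")
    ratios = num[valid] / den[valid]
    return IncorporationResult(
        ratio_mean=float(ratios.mean()),
        ratio_sd=float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
        n=int(ratios.size),
        labeled_name=labeled_name,
        reference_name=reference_name,
    )


def region_fold_change(
    image: IonImage, mask_a: RegionMask, mask_b: RegionMask
) -> float:
    """Ratio of mean intensity in region A over region B (missing excluded)."""
    mask_a.require_shape(image.values.shape)
    mask_b.require_shape(image.values.shape)
    if mask_a.n_pixels == 0 or mask_b.n_pixels == 0:
        raise ValueError("both regions must contain at least one pixel")
    if np.any(mask_a.values & mask_b.values):
        raise ValueError("regions must be disjoint")
    mean_a = np.nanmean(image.values[mask_a.values])
    mean_b = np.nanmean(image.values[mask_b.values])
    if not np.isfinite(mean_b) or mean_b == 0:
        raise ValueError("reference region has zero or undefined mean")
    return float(mean_a / mean_b)


def remodeling_abundances(
    table: pd.DataFrame, t0_value: float
) -> pd.DataFrame:
    """Per-species abundance relative to the administered dose at t=0.

    ``table`` is a species x sample intensity table (rows = species,
    columns = samples); every intensity is divided by ``t0_value`` and
    expressed in percent, then averaged across samples.  Returns a frame
    indexed by species with columns ``mean_pct``, ``sd_pct`` (sample SD)
    and ``n``.
    """
    if t0_value <= 0:
        raise ValueError("t0 reference value must be positive")
    if (table.to_numpy() < 0).any():
        raise ValueError("intensity table must be non-negative")
    rel = table / t0_value * 100.0
    return pd.DataFrame(
        {
            "mean_pct": rel.mean(axis=1),
            "sd_pct": rel.std(axis=1, ddof=1).fillna(0.0),
            "n": rel.notna().sum(axis=1),
        }
    )


def group_compare(
    values_a, values_b, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance by default).

    Returns ``(t statistic, two-sided p)``.  ``equal_var=False`` switches to
    Welch's unequal-variance form.  Both groups need n >= 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if equal_var:
        na, nb = a.size, b.size
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
    if se == 0:
        # identical-variance degenerate case: no evidence of difference
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    t = float((a.mean() - b.mean()) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p
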