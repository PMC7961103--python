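"""MSI spectral processing: lock-mass recalibration, peak picking and ppm
alignment, mean spectra, ion-image extraction with TIC normalization,
quantile hotspot clipping, ratio images, and RGB channel overlays.

Defaults mirror common high-resolution MALDI-MSI practice: a multiplicative
(proportional-drift) lock-mass correction searched within +-20 ppm, peak
picking at a 0.05% relative intensity threshold with a 0.5% minimum pixel
frequency and 3 ppm alignment tolerance, TIC-normalized images, and 99%
quantile hotspot removal for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from matplotlib.colors import to_rgb

from .msio import MSIDataset, Spectrum

__all__ = [
    "PeakTable",
    "IonImage",
    "RegionMask",
    "recalibrate_lock_mass",
    "recalibrate_dataset",
    "pick_and_align_peaks",
    "mean_spectrum",
    "extract_ion_image",
    "hotspot_clip",
    "ratio_image",
    "overlay_channels",
    "LOCK_MASS_PC32_0_NA",
]

#: Theoretical sodiated PC32:0 m/z, the customary lung-surfactant lock mass.
LOCK_MASS_PC32_0_NA = 756.551374

DEFAULT_INTENSITY_THRESHOLD = 0.0005  # 0.05% of the dataset base peak
DEFAULT_MIN_FREQUENCY = 0.005  # peak present in >= 0.5% of pixels
DEFAULT_ALIGN_TOL_PPM = 3.0
DEFAULT_LOCK_SEARCH_PPM = 20.0
DEFAULT_HOTSPOT_QUANTILE = 0.99


@dataclass
class PeakTable:
    """Aligned peak features: consensus m/z plus a feature x pixel matrix.

    Column order matches the dataset's spectrum (acquisition) order.
    """

    mz: np.ndarray  # (n_features,), sorted ascending
    intensities: np.ndarray  # (n_features, n_pixels)
    pixel_xy: list[tuple[int, int]]
    relative_intensity_threshold: float
    min_frequency: float
    align_tol_ppm: float

    @property
    def n_features(self) -> int:
        return len(self.mz)

    @property
    def frequencies(self) -> np.ndarray:
        """Fraction of pixels in which each feature has nonzero intensity."""
        return (self.intensities > 0).mean(axis=1)


@dataclass
class IonImage:
    """2-D intensity grid (rows x columns) for one m/z window.

    Missing pixels (no spectrum, or zero TIC under TIC normalization) are
    NaN, never silently zero.
    """

    values: np.ndarray
    target_mz: float
    tol_ppm: float
    normalization: str = "none"  # none | tic | denominator
    clipped_quantile: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ion image must be a 2-D grid")


@dataclass
class RegionMask:
    """Boolean pixel selector with the same grid shape as the images it cuts."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("region mask must be a 2-D grid")

    def require_shape(self, shape: tuple[int, int]) -> None:
        if self.values.shape != shape:
            raise ValueError(f"mask shape {self.values.shape} != image shape {shape}")

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# Recalibration
# ---------------------------------------------------------------------------


def recalibrate_lock_mass(
    spectrum: Spectrum,
    lock_mz: float = LOCK_MASS_PC32_0_NA,
    search_tol_ppm: float = DEFAULT_LOCK_SEARCH_PPM,
) -> tuple[Spectrum, bool]:
    """Recalibrate one spectrum against a lock mass.

    The most intense peak within +-``search_tol_ppm`` of ``lock_mz`` defines a
    multiplicative correction ``lock_mz / observed`` applied to the whole m/z
    axis (proportional ppm-drift model).  If no peak lies in the window the
    spectrum is returned unchanged with ``found=False`` — a flagged, non-fatal
    outcome.
    """
    if lock_mz <= 0:
        raise ValueError("lock m/z must be positive")
    half = lock_mz * search_tol_ppm * 1e-6
    lo = np.searchsorted(spectrum.mz, lock_mz - half, side="left")
    hi = np.searchsorted(spectrum.mz, lock_mz + half, side="right")
    if hi <= lo:
        return spectrum, False
    best = lo + int(np.argmax(spectrum.intensities[lo:hi]))
    factor = lock_mz / spectrum.mz[best]
    return (
        Spectrum(spectrum.mz * factor, spectrum.intensities, spectrum.pixel_xy),
        True,
    )


def recalibrate_dataset(
    dataset: MSIDataset,
    lock_mz: float = LOCK_MASS_PC32_0_NA,
    search_tol_ppm: float = DEFAULT_LOCK_SEARCH_PPM,
) -> tuple[MSIDataset, int]:
    """Apply lock-mass recalibration per pixel; returns (dataset, n_found)."""
    spectra: list[Spectrum] = []
    n_found = 0
    for s in dataset.spectra:
        rec, found = recalibrate_lock_mass(s, lock_mz, search_tol_ppm)
        spectra.append(rec)
        n_found += found
    meta = dict(dataset.metadata)
    meta["lock_mass"] = lock_mz
    meta["lock_found_pixels"] = n_found
    return (
        MSIDataset(spectra, dataset.grid_shape, dataset.pixel_size_um, meta),
        n_found,
    )


# ---------------------------------------------------------------------------
# Peak picking and alignment
# ---------------------------------------------------------------------------


def pick_and_align_peaks(
    dataset: MSIDataset,
    relative_intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
    align_tol_ppm: float = DEFAULT_ALIGN_TOL_PPM,
) -> PeakTable:
    """Pick per-pixel peaks and align them across pixels into features.

    Peaks below ``relative_intensity_threshold`` x (dataset base-peak
    intensity) are discarded, the survivors are clustered greedily — clusters
    are seeded from the most intense unassigned peak and absorb every
    unassigned peak within ``align_tol_ppm`` of the seed m/z — and each
    cluster's consensus m/z is the intensity-weighted mean of its members.
    Clusters present in fewer than ``min_frequency`` of pixels are dropped.
    Features are returned sorted by consensus m/z.
    """
    if len(dataset) == 0:
        raise ValueError("cannot pick peaks from an empty dataset")
    n_pixels = len(dataset)
    base = dataset.base_peak_intensity
    floor = relative_intensity_threshold * base

    all_mz: list[np.ndarray] = []
    all_int: list[np.ndarray] = []
    all_pix: list[np.ndarray] = []
    for i, s in enumerate(dataset.spectra):
        keep = s.intensities >= floor
        all_mz.append(s.mz[keep])
        all_int.append(s.intensities[keep])
        all_pix.append(np.full(int(keep.sum()), i, dtype=np.int64))
    mz = np.concatenate(all_mz) if all_mz else np.empty(0)
    inten = np.concatenate(all_int) if all_int else np.empty(0)
    pix = np.concatenate(all_pix) if all_pix else np.empty(0, dtype=np.int64)

    order_mz = np.argsort(mz, kind="stable")
    mz_s, int_s, pix_s = mz[order_mz], inten[order_mz], pix[order_mz]
    assigned = np.zeros(len(mz_s), dtype=bool)

    features: list[tuple[float, np.ndarray]] = []
    for j in np.argsort(int_s, kind="stable")[::-1]:
        if assigned[j]:
            continue
        seed = mz_s[j]
        half = seed * align_tol_ppm * 1e-6
        lo = np.searchsorted(mz_s, seed - half, side="left")
        hi = np.searchsorted(mz_s, seed + half, side="right")
        members = np.arange(lo, hi)[~assigned[lo:hi]]
        assigned[lo:hi] = True
        w = int_s[members]
        consensus = float(np.average(mz_s[members], weights=w)) if w.sum() > 0 else float(seed)
        vec = np.zeros(n_pixels)
        np.add.at(vec, pix_s[members], int_s[members])
        features.append((consensus, vec))

    kept = [
        (cmz, vec)
        for cmz, vec in features
        if (vec > 0).mean() >= min_frequency and vec.max() >= floor
    ]
    kept.sort(key=lambda t: t[0])
    return PeakTable(
        mz=np.array([c for c, _ in kept]),
        intensities=(
            np.vstack([v for _, v in kept]) if kept else np.empty((0, n_pixels))
        ),
        pixel_xy=[s.pixel_xy for s in dataset.spectra],
        relative_intensity_threshold=relative_intensity_threshold,
        min_frequency=min_frequency,
        align_tol_ppm=align_tol_ppm,
    )


def mean_spectrum(dataset: MSIDataset, peak_table: PeakTable) -> Spectrum:
    """Dataset-mean intensity per aligned feature (absent pixel counts as 0)."""
    if peak_table.intensities.shape[1] != len(dataset):
        raise ValueError("peak table does not match dataset pixel count")
    return Spectrum(
        peak_table.mz, peak_table.intensities.mean(axis=1), pixel_xy=(0, 0)
    )


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def extract_ion_image(
    dataset: MSIDataset,
    target_mz: float,
    tol_ppm: float = DEFAULT_ALIGN_TOL_PPM,
    normalization: str = "tic",
) -> IonImage:
    """Extract the ion image for a symmetric, closed +-``tol_ppm`` m/z window.

    Each pixel is the sum of centroid intensities inside the window; in TIC
    mode it is divided by that pixel's total ion current (zero-TIC pixels
    become missing).  Grid pixels without a spectrum are missing (NaN).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if normalization not in ("none", "tic"):
        raise ValueError(f"unknown normalization {normalization!r}")
    ncols, nrows = dataset.grid_shape
    values = np.full((nrows, ncols), np.nan)
    half = target_mz * tol_ppm * 1e-6
    for s in dataset.spectra:
        lo = np.searchsorted(s.mz, target_mz - half, side="left")
        hi = np.searchsorted(s.mz, target_mz + half, side="right")
        signal = float(s.intensities[lo:hi].sum())
        x, y = s.pixel_xy
        if normalization == "tic":
            t = s.tic
            values[y, x] = signal / t if t > 0 else np.nan
        else:
            values[y, x] = signal
    return IonImage(values, target_mz, tol_ppm, normalization)


def hotspot_clip(
    image: IonImage, high_quantile: float = DEFAULT_HOTSPOT_QUANTILE
) -> IonImage:
    """Clip intensities above the ``high_quantile`` quantile of valid pixels.

    Uses linear interpolation between order statistics (the "type 7" rule).
    Values at or below the quantile are untouched and an image already
    clipped at this quantile is returned as-is (clipping flattens the upper
    tail, so re-deriving the quantile from clipped values would erode the
    image further); the operation is therefore idempotent and never
    increases any pixel.
    """
    if not (0 < high_quantile <= 1):
        raise ValueError("high_quantile must be in (0, 1]")
    if image.clipped_quantile is not None and image.clipped_quantile <= high_quantile:
        return replace(image)
    valid = image.values[np.isfinite(image.values)]
    if valid.size == 0:
        raise ValueError("cannot clip an image with no valid pixels")
    q = float(np.quantile(valid, high_quantile))
    clipped = np.where(image.values > q, q, image.values)  # NaN stays NaN
    return replace(image, values=clipped, clipped_quantile=high_quantile)


def ratio_image(numerator: IonImage, denominator: IonImage) -> IonImage:
    """Pixelwise numerator/denominator; denominator-zero or missing -> missing.

    Both images must share the grid shape and the same normalization state
    (TIC factors cancel in the ratio either way, but mixing states is almost
    always a mistake).
    """
    if numerator.values.shape != denominator.values.shape:
        raise ValueError("ratio images require matching grid shapes")
    if numerator.normalization != denominator.normalization:
        raise ValueError("numerator and denominator must share normalization")
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = numerator.values / denominator.values
    vals[~np.isfinite(vals)] = np.nan
    vals[denominator.values == 0] = np.nan
    return IonImage(
        vals, numerator.target_mz, numerator.tol_ppm, normalization="denominator"
    )


def overlay_channels(
    images: Sequence[IonImage],
    colors: Sequence[str],
    high_quantile: float | None = DEFAULT_HOTSPOT_QUANTILE,
) -> np.ndarray:
    """Compose up to three ion images into an RGB grid.

    Each image is hotspot-clipped (unless ``high_quantile`` is None), min-max
    scaled to [0, 1], and multiplied into its color's RGB components; missing
    pixels render black in that channel.
    """
    if not 1 <= len(images) <= 3:
        raise ValueError("overlay supports 1-3 channels")
    if len(colors) != len(images):
        raise ValueError("need one color per image")
    shape = images[0].values.shape
    rgb = np.zeros((*shape, 3))
    for img, color in zip(images, colors):
        if img.values.shape != shape:
            raise ValueError("all overlay images must share one grid shape")
        if high_quantile is not None:
            img = hotspot_clip(img, high_quantile)
        vals = img.values.copy()
        finite = np.isfinite(vals)
        vmin = vals[finite].min() if finite.any() else 0.0
        vmax = vals[finite].max() if finite.any() else 0.0
        scaled = np.zeros(shape)
        if vmax > vmin:
            scaled[finite] = (vals[finite] - vmin) / (vmax - vmin)
        elif finite.any():
            scaled[finite] = 1.0
        r, g, b = to_rgb(color)
        rgb += scaled[..., None] * np.array([r, g, b])
    return np.clip(rgb, 0.0, 1.0)
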