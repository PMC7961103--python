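"""Synthetic lung-section phantom and shotgun-profile generator.

Emulates the measured structure of a dual-tracer MALDI-MSI lung experiment
with known ground truth: a parenchyma background carrying the surfactant PC
panel, elliptical bronchiole structures enriched in polyunsaturated PC
(PC36:4, PC38:6) and devoid of exogenous surfactant, and a deposition blob
where instilled surfactant raises DPPC 2.5-fold and contributes U13C-DPPC at
the dosed isotopic enrichment.  Newly synthesized D9-choline-labeled PC runs
at ~1% of the endogenous pool and the 13C24 Lands-cycle re-acylation product
at ~0.1% of DPPC.  Every ion is emitted as H+/Na+/K+ adducts with its
natural-abundance isotopologue envelope, per-spectrum linear ppm drift, and
multiplicative log-normal noise.

The noise model is hierarchical: each lipid pool receives an independent
per-pixel log-normal factor (MALDI matrix/ablation variability, CV 0.2 by
default), and a labeled isotopologue shares its parent pool's factor — the
ionization physics that makes isotopologue ratio imaging robust — plus a
small independent channel jitter (CV 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mass import (
    LABEL_13C24,
    LABEL_D9,
    Adduct,
    LipidSpecies,
    isotopologue_envelope,
    u13c_label,
)
from .msio import MSIDataset, Spectrum

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "generate_phantom",
    "generate_shotgun_profiles",
    "DEFAULT_SHOTGUN_MEANS",
]

#: Per-species (parenchyma, bronchiole) base intensities, arbitrary units.
#: PC36:4/PC38:6 are bronchiole-restricted; DPPC (PC32:0) dominates.
DEFAULT_SPECIES_PANEL: dict[str, tuple[float, float]] = {
    "PC32:0": (100.0, 60.0),
    "PC32:1": (45.0, 28.0),
    "PC34:1": (35.0, 35.0),
    "PC34:2": (30.0, 30.0),
    "PC36:4": (0.0, 25.0),
    "PC38:6": (0.0, 18.0),
}

#: Mean remodeling-product abundances relative to the U13C-DPPC dose at t=0,
#: in percent, for the shotgun-profile generator (alveolar-macrophage shape).
DEFAULT_SHOTGUN_MEANS: dict[str, float] = {
    "U13C-DPPC": 38.7,
    "13C24-PC16:0_20:4": 36.8,
    "13C24-PC16:0_22:6": 24.5,
}


@dataclass
class PhantomConfig:
    """Ground-truth layout and signal model of the lung phantom."""

    grid_shape: tuple[int, int] = (64, 64)  # (n_columns, n_rows)
    pixel_size_um: float = 40.0
    #: elliptical bronchiole lumina as (cx, cy, rx, ry) in grid fractions
    bronchioles: tuple[tuple[float, float, float, float], ...] = (
        (0.22, 0.32, 0.11, 0.08),
        (0.70, 0.68, 0.08, 0.11),
    )
    #: surfactant deposition blob (cx, cy, rx, ry) in grid fractions
    deposition: tuple[float, float, float, float] = (0.62, 0.22, 0.20, 0.16)
    species_panel: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_PANEL)
    )
    #: DPPC multiplier inside the deposition blob (exogenous surfactant)
    deposition_enhancement: float = 2.5
    #: newly synthesized (Kennedy-pathway) fraction of the endogenous pool
    d9_fraction: float = 0.01
    #: 13C24-PC16:0_20:4 re-acylation product relative to local DPPC signal
    remodel_fraction: float = 0.001
    #: U13C-DPPC fraction of the exogenous (deposited) DPPC; 0.0755 matches a
    #: Poractant alfa-type dose, 0.0287 a CHF5633-type dose
    u13c_enrichment: float = 0.0755
    adduct_ratios: dict[str, float] = field(
        default_factory=lambda: {"H": 0.35, "Na": 1.0, "K": 0.45}
    )
    envelope_peaks: int = 3
    noise_cv: float = 0.2
    channel_cv: float = 0.02
    drift_ppm: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        ncols, nrows = self.grid_shape
        if ncols < 4 or nrows < 4:
            raise ValueError("phantom grid must be at least 4 x 4")
        for frac in (self.d9_fraction, self.remodel_fraction, self.u13c_enrichment):
            if not 0 <= frac <= 1:
                raise ValueError("label fractions must lie in [0, 1]")
        if any(v < 0 for pair in self.species_panel.values() for v in pair):
            raise ValueError("species abundances must be non-negative")
        if self.deposition_enhancement < 1:
            raise ValueError("deposition enhancement must be >= 1")
        if self.noise_cv < 0 or self.channel_cv < 0 or self.drift_ppm < 0:
            raise ValueError("noise and drift amplitudes must be >= 0")
        if self.envelope_peaks < 1:
            raise ValueError("envelope depth must be >= 1")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    masks: dict[str, np.ndarray]  # parenchyma / bronchiole / deposition
    channel_truth: dict[str, np.ndarray]  # noisy M+0 pool intensity per pixel
    expected_maps: dict[str, np.ndarray]  # noiseless per-species base maps
    ion_mz: dict[tuple[str, str], float]  # (channel name, adduct) -> m/z
    drift_ppm_map: np.ndarray  # per-pixel true calibration drift
    config: PhantomConfig


def _ellipse_mask(
    ncols: int, nrows: int, cx: float, cy: float, rx: float, ry: float
) -> np.ndarray:
    x = (np.arange(ncols) + 0.5) / ncols
    y = (np.arange(nrows) + 0.5) / nrows
    xx, yy = np.meshgrid(x, y)
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _lognormal_field(
    rng: np.random.Generator, shape: tuple[int, int], cv: float
) -> np.ndarray:
    """Mean-1 multiplicative log-normal field with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def generate_phantom(config: PhantomConfig | None = None) -> tuple[MSIDataset, GroundTruth]:
    """Generate the lung phantom dataset plus its ground truth.

    Deterministic for a given config (one seeded generator drives all
    randomness); the seed is recorded in the dataset metadata.
    """
    config = config or PhantomConfig()
    config.validate()
    ncols, nrows = config.grid_shape
    rng = np.random.default_rng(config.seed)

    bron = np.zeros((nrows, ncols), dtype=bool)
    for cx, cy, rx, ry in config.bronchioles:
        bron |= _ellipse_mask(ncols, nrows, cx, cy, rx, ry)
    depo = _ellipse_mask(ncols, nrows, *config.deposition) & ~bron
    paren = ~bron
    masks = {"parenchyma": paren, "bronchiole": bron, "deposition": depo}

    # --- noiseless base maps -------------------------------------------------
    expected: dict[str, np.ndarray] = {}
    for name, (a_par, a_bron) in config.species_panel.items():
        expected[name] = np.where(bron, a_bron, a_par).astype(float)
    dppc_endo = expected["PC32:0"].copy()
    dppc_excess = np.where(
        depo, dppc_endo * (config.deposition_enhancement - 1.0), 0.0
    )
    expected["PC32:0"] = dppc_endo + dppc_excess

    # --- noisy pool intensities (M+0 channel scale) --------------------------
    pools: dict[str, np.ndarray] = {
        name: expected[name] * _lognormal_field(rng, (nrows, ncols), config.noise_cv)
        for name in config.species_panel
        if name != "PC32:0"
    }
    endo_noisy = dppc_endo * _lognormal_field(rng, (nrows, ncols), config.noise_cv)
    exo_noisy = dppc_excess * _lognormal_field(rng, (nrows, ncols), config.noise_cv)
    pools["PC32:0"] = endo_noisy + exo_noisy

    jitter = lambda: _lognormal_field(rng, (nrows, ncols), config.channel_cv)
    labeled: dict[str, np.ndarray] = {
        # de novo synthesis traces the endogenous pool only
        "D9-PC32:0": config.d9_fraction * endo_noisy * jitter(),
        "D9-PC32:1": config.d9_fraction * pools["PC32:1"] * jitter(),
        # exogenous tracer rides on the deposited (excess) surfactant
        "U13C-PC32:0": config.u13c_enrichment * exo_noisy * jitter(),
        # Lands-cycle product tracks local DPPC but is absent from bronchioles
        "13C24-PC16:0_20:4": (
            config.remodel_fraction * pools["PC32:0"] * jitter() * paren
        ),
    }
    channel_truth = {**pools, **labeled}

    # --- ion channels: species x adduct x envelope peak ----------------------
    species_objects = {
        name: LipidSpecies.parse(name) for name in config.species_panel
    }
    species_objects["D9-PC32:0"] = LipidSpecies.parse("PC32:0", LABEL_D9)
    species_objects["D9-PC32:1"] = LipidSpecies.parse("PC32:1", LABEL_D9)
    species_objects["U13C-PC32:0"] = LipidSpecies.parse("PC32:0", u13c_label(40))
    species_objects["13C24-PC16:0_20:4"] = LipidSpecies.parse(
        "PC16:0_20:4", LABEL_13C24
    )

    ion_mz: dict[tuple[str, str], float] = {}
    peak_mz: list[float] = []
    peak_maps: list[np.ndarray] = []
    for name, sp in species_objects.items():
        amount = channel_truth[name]
        if amount.max() <= 0:
            continue
        envelope = isotopologue_envelope(sp.formula(), config.envelope_peaks)
        for kind, ratio in config.adduct_ratios.items():
            if ratio <= 0:
                continue
            mz0 = sp.mz(Adduct(kind))
            ion_mz[(name, kind)] = mz0
            for offset, abundance in envelope:
                if abundance <= 0:
                    continue
                peak_mz.append(mz0 + offset)
                peak_maps.append(amount * ratio * abundance)

    order = np.argsort(peak_mz)
    mz_sorted = np.array(peak_mz)[order]
    stack = np.stack([peak_maps[i] for i in order])  # (n_peaks, nrows, ncols)
    # merge coincident channels (< 1 uDa apart) so spectra stay strictly sorted
    if len(mz_sorted) > 1:
        group = np.concatenate([[0], np.cumsum(np.diff(mz_sorted) >= 1e-6)])
        if group[-1] + 1 < len(mz_sorted):
            merged_mz = np.array(
                [mz_sorted[group == g].mean() for g in range(group[-1] + 1)]
            )
            merged_stack = np.stack(
                [stack[group == g].sum(axis=0) for g in range(group[-1] + 1)]
            )
            mz_sorted, stack = merged_mz, merged_stack

    # --- assemble per-pixel spectra with linear acquisition drift ------------
    n_px = nrows * ncols
    drift_map = np.zeros((nrows, ncols))
    spectra: list[Spectrum] = []
    i = 0
    for y in range(nrows):
        for x in range(ncols):
            frac = i / (n_px - 1) if n_px > 1 else 0.0
            drift = config.drift_ppm * (2.0 * frac - 1.0)
            drift_map[y, x] = drift
            inten = stack[:, y, x]
            keep = inten > 0
            mz_px = mz_sorted[keep] * (1.0 + drift * 1e-6)
            spectra.append(Spectrum(mz_px, inten[keep], (x, y)))
            i += 1

    dataset = MSIDataset(
        spectra=spectra,
        grid_shape=config.grid_shape,
        pixel_size_um=config.pixel_size_um,
        metadata={
            "generator": "pctracer lung phantom",
            "seed": config.seed,
            "drift_ppm": config.drift_ppm,
            "noise_cv": config.noise_cv,
        },
    )
    truth = GroundTruth(
        masks=masks,
        channel_truth=channel_truth,
        expected_maps=expected,
        ion_mz=ion_mz,
        drift_ppm_map=drift_map,
        config=config,
    )
    return dataset, truth


def generate_shotgun_profiles(
    n_per_group: int = 8,
    group_means: dict[str, float] | None = None,
    cv: float = 0.2,
    seed: int = 0,
    t0_value: float = 100.0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a shotgun-style species x sample intensity table.

    Each sample's intensity for a species is drawn log-normally around
    ``group_means[species] / 100 * t0_value`` with coefficient of variation
    ``cv`` (``cv=0`` reproduces the means exactly).  Returns the table and a
    ground-truth dict with the configured means and the t0 reference value.
    """
    if n_per_group < 2:
        raise ValueError("need at least two samples per group")
    means = dict(group_means) if group_means is not None else dict(DEFAULT_SHOTGUN_MEANS)
    rng = np.random.default_rng(seed)
    rows = {}
    for name, pct in means.items():
        base = pct / 100.0 * t0_value
        factors = (
            np.ones(n_per_group)
            if cv <= 0
            else _lognormal_field(rng, (1, n_per_group), cv).ravel()
        )
        rows[name] = base * factors
    table = pd.DataFrame(
        rows, index=[f"sample{i + 1}" for i in range(n_per_group)]
    ).T
    truth = {"group_means_pct": means, "t0_value": t0_value, "cv": cv, "seed": seed}
    return table, truth
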