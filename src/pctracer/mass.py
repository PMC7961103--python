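"""Exact-mass engine for phosphatidylcholine isotope-tracer work.

Elemental compositions, isotope-label substitution (deuterium and 13C),
monoisotopic and adduct m/z arithmetic, ppm errors, natural-abundance
isotopologue envelopes, and the resolving power needed to separate two ions.

All masses come from the atomic-mass constants below (CODATA/AME values);
singly charged cations subtract one electron mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "ISOTOPE_MASS",
    "MASS_13C_SHIFT",
    "MASS_D_SHIFT",
    "ElementalFormula",
    "LabelSpec",
    "LipidSpecies",
    "Adduct",
    "MassMeasurement",
    "InvalidSpeciesError",
    "LabelOverflowError",
    "UnsupportedElementError",
    "pc_sum_formula",
    "apply_label",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "isotopologue_envelope",
    "resolving_power_required",
]

# ---------------------------------------------------------------------------
# Atomic constants (single source of truth for all mass arithmetic)
# ---------------------------------------------------------------------------

ELECTRON_MASS = 0.000548579909  # Da

#: Monoisotopic (principal-isotope) masses; "13C" and "D" are the fixed
#: heavy isotopes introduced by labeling and contribute no further
#: natural-abundance substitution.
ISOTOPE_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "D": 2.0141017781,
    "C": 12.0,
    "13C": 13.0033548351,
    "N": 14.0030740044,
    "O": 15.9949146196,
    "P": 30.9737619984,
    "Na": 22.9897692820,
    "K": 38.9637064864,
}

MASS_13C_SHIFT = ISOTOPE_MASS["13C"] - ISOTOPE_MASS["C"]  # 1.0033548 Da
MASS_D_SHIFT = ISOTOPE_MASS["D"] - ISOTOPE_MASS["H"]  # 1.0062768 Da

#: Natural isotope patterns per element as (neutron shift, abundance,
#: mass shift from the principal isotope).  Monoisotopic elements and the
#: label isotopes map to the identity pattern.
_NATURAL_PATTERN: dict[str, list[tuple[int, float, float]]] = {
    "H": [(0, 0.999885, 0.0), (1, 0.000115, MASS_D_SHIFT)],
    "C": [(0, 0.9893, 0.0), (1, 0.0107, MASS_13C_SHIFT)],
    "N": [(0, 0.99636, 0.0), (1, 0.00364, 15.0001088989 - ISOTOPE_MASS["N"])],
    "O": [
        (0, 0.99757, 0.0),
        (1, 0.00038, 16.9991317565 - ISOTOPE_MASS["O"]),
        (2, 0.00205, 17.9991596129 - ISOTOPE_MASS["O"]),
    ],
    "K": [
        (0, 0.932581, 0.0),
        (1, 0.000117, 39.9639981660 - ISOTOPE_MASS["K"]),
        (2, 0.067302, 40.9618252579 - ISOTOPE_MASS["K"]),
    ],
    # monoisotopic in nature / already-substituted label sites
    "P": [(0, 1.0, 0.0)],
    "Na": [(0, 1.0, 0.0)],
    "D": [(0, 1.0, 0.0)],
    "13C": [(0, 1.0, 0.0)],
}


class InvalidSpeciesError(ValueError):
    """Chemically impossible lipid description (negative counts, too many DB)."""


class LabelOverflowError(ValueError):
    """Isotope substitution exceeds the atoms available in the formula."""


class UnsupportedElementError(KeyError):
    """Element symbol outside the supported mass table."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_SYMBOL_ORDER = ("13C", "C", "D", "H", "N", "O", "P", "Na", "K")


@dataclass(frozen=True)
class ElementalFormula:
    """Element/isotope symbol -> count map; the substrate of mass arithmetic.

    Counts are non-negative; an absent symbol means zero.  Total carbon is
    ``C + 13C`` and total hydrogen ``H + D``, so labeling moves counts between
    the light and heavy keys without changing atom totals.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sym, n in dict(self.counts).items():
            if sym not in ISOTOPE_MASS:
                raise UnsupportedElementError(sym)
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {sym}: {n}")
            if n:
                clean[sym] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) - n
        return ElementalFormula(merged)  # raises if any count goes negative

    @property
    def total_carbon(self) -> int:
        return self["C"] + self["13C"]

    @property
    def total_hydrogen(self) -> int:
        return self["H"] + self["D"]

    def __str__(self) -> str:
        parts = []
        for sym in _SYMBOL_ORDER:
            n = self[sym]
            if not n:
                continue
            shown = "[13C]" if sym == "13C" else sym
            parts.append(f"{shown}{n if n > 1 else ''}")
        return "".join(parts) or "(empty)"

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse strings like ``C40H80NO8P`` or ``[13C]24C20H80NO8P``."""
        counts: dict[str, int] = {}
        pos = 0
        pattern = re.compile(r"(\[13C\]|13C|Na|K|C|D|H|N|O|P)(\d*)")
        while pos < len(text):
            m = pattern.match(text, pos)
            if m is None:
                raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
            sym = "13C" if m.group(1) in ("[13C]", "13C") else m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[sym] = counts.get(sym, 0) + n
            pos = m.end()
        return cls(counts)


@dataclass(frozen=True)
class LabelSpec:
    """An isotope-label state: how many 12C->13C and H->D substitutions.

    ``(0, 0)`` is the unlabeled identity.  ``name`` identifies the tracer
    ("D9", "13C5", "13C24", "U13C") and drives MS/MS label routing.
    """

    n13C: int = 0
    nD: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n13C < 0 or self.nD < 0:
            raise ValueError("label substitution counts must be >= 0")

    @property
    def is_unlabeled(self) -> bool:
        return self.n13C == 0 and self.nD == 0

    @property
    def mass_shift(self) -> float:
        """Exact m/z shift this label adds to any ion of the species."""
        return self.n13C * MASS_13C_SHIFT + self.nD * MASS_D_SHIFT


UNLABELED = LabelSpec(0, 0, "")
#: methyl-D9-choline label: three CD3 groups on the headgroup nitrogen.
LABEL_D9 = LabelSpec(0, 9, "D9")
#: 13C5-choline from tracer headgroup recycling (all five choline carbons).
LABEL_13C5 = LabelSpec(5, 0, "13C5")
#: 13C24-palmitoyl-lysoPC backbone re-acylated with an unlabeled chain:
#: glycerol (3) + choline (5) + palmitoyl (16) carbons are heavy.
LABEL_13C24 = LabelSpec(24, 0, "13C24")


def u13c_label(total_carbons_with_headgroup: int) -> LabelSpec:
    """Universal 13C label for a PC with the given *total* carbon count
    (acyl carbons + 8 headgroup/backbone carbons)."""
    return LabelSpec(total_carbons_with_headgroup, 0, "U13C")


_SPECIES_RE = re.compile(r"^PC(\d+):(\d+)$")
_CHAINS_RE = re.compile(r"^PC(\d+):(\d+)([_/])(\d+):(\d+)$")


@dataclass(frozen=True)
class LipidSpecies:
    """A diacyl PC at sum-composition or chain-resolved level, plus its label.

    ``chains`` (if given) must sum to the totals; ``sn_defined`` selects the
    "/" (sn-resolved) versus "_" (unresolved) rendering.
    """

    total_carbons: int
    total_double_bonds: int
    chains: tuple[tuple[int, int], ...] | None = None
    sn_defined: bool = False
    label: LabelSpec = UNLABELED
    lipid_class: str = "PC"

    def __post_init__(self) -> None:
        if self.lipid_class != "PC":
            raise InvalidSpeciesError(f"only PC in scope, got {self.lipid_class}")
        if self.chains is not None:
            nc = sum(c for c, _ in self.chains)
            nd = sum(d for _, d in self.chains)
            if (nc, nd) != (self.total_carbons, self.total_double_bonds):
                raise InvalidSpeciesError(
                    f"chains {self.chains} do not sum to "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )
        pc_sum_formula(self.total_carbons, self.total_double_bonds)  # validates

    @classmethod
    def parse(cls, text: str, label: LabelSpec = UNLABELED) -> "LipidSpecies":
        """Parse "PC32:0", "PC16:0_20:4" or "PC16:0/16:0"."""
        m = _CHAINS_RE.match(text)
        if m:
            c1, d1, sep, c2, d2 = m.groups()
            chains = ((int(c1), int(d1)), (int(c2), int(d2)))
            return cls(
                total_carbons=chains[0][0] + chains[1][0],
                total_double_bonds=chains[0][1] + chains[1][1],
                chains=chains,
                sn_defined=(sep == "/"),
                label=label,
            )
        m = _SPECIES_RE.match(text)
        if m:
            return cls(int(m.group(1)), int(m.group(2)), label=label)
        raise InvalidSpeciesError(f"unrecognized PC species {text!r}")

    @property
    def name(self) -> str:
        if self.chains:
            sep = "/" if self.sn_defined else "_"
            body = sep.join(f"{c}:{d}" for c, d in self.chains)
        else:
            body = f"{self.total_carbons}:{self.total_double_bonds}"
        prefix = f"{self.label.name}-" if self.label.name else ""
        return f"{prefix}PC{body}"

    def formula(self) -> ElementalFormula:
        return apply_label(
            pc_sum_formula(self.total_carbons, self.total_double_bonds), self.label
        )

    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula())

    def mz(self, adduct: "Adduct") -> float:
        return adduct_mz(self.neutral_mass(), adduct)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Adduct:
    """Singly charged cation adduct (+H, +Na or +K); electron mass subtracted."""

    kind: str
    charge: int = 1

    _DELTAS = {
        "H": ISOTOPE_MASS["H"] - ELECTRON_MASS,
        "Na": ISOTOPE_MASS["Na"] - ELECTRON_MASS,
        "K": ISOTOPE_MASS["K"] - ELECTRON_MASS,
    }

    def __post_init__(self) -> None:
        kind = self.kind.lstrip("+")
        object.__setattr__(self, "kind", kind)
        if kind not in self._DELTAS:
            raise ValueError(f"unsupported adduct +{kind} (use H, Na or K)")
        if self.charge != 1:
            raise ValueError("only singly charged cations are modeled")

    @property
    def mass_delta(self) -> float:
        return self._DELTAS[self.kind]

    def __str__(self) -> str:
        return f"+{self.kind}"


ADDUCT_H = Adduct("H")
ADDUCT_NA = Adduct("Na")
ADDUCT_K = Adduct("K")


@dataclass(frozen=True)
class MassMeasurement:
    """An observed/theoretical m/z pair and the signed ppm error between them."""

    observed_mz: float
    theoretical_mz: float

    @property
    def ppm_error(self) -> float:
        return ppm_error(self.observed_mz, self.theoretical_mz)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def pc_sum_formula(total_carbons: int, double_bonds: int) -> ElementalFormula:
    """Elemental composition of an unlabeled diacyl PC at sum-composition level.

    For n acyl carbons and d double bonds the molecule is
    C(n+8) H(2n+16-2d) N O8 P: the glycerophosphocholine backbone contributes
    8 carbons, the acyl chains n, and each double bond removes two hydrogens.
    """
    if total_carbons < 2:
        raise InvalidSpeciesError("diacyl PC needs at least 2 acyl carbons")
    if double_bonds < 0:
        raise InvalidSpeciesError("double bond count must be >= 0")
    n_h = 2 * total_carbons + 16 - 2 * double_bonds
    # each acyl chain of c carbons supports at most (c-1) C=C positions;
    # the coarse sum-composition bound is total_carbons - 2
    if double_bonds > total_carbons - 2:
        raise InvalidSpeciesError(
            f"{double_bonds} double bonds infeasible for {total_carbons} acyl carbons"
        )
    return ElementalFormula(
        {"C": total_carbons + 8, "H": n_h, "N": 1, "O": 8, "P": 1}
    )


def apply_label(formula: ElementalFormula, label: LabelSpec) -> ElementalFormula:
    """Move ``n13C`` carbons to 13C and ``nD`` hydrogens to D; atoms conserved."""
    if label.n13C > formula["C"]:
        raise LabelOverflowError(
            f"cannot place {label.n13C} x 13C in {formula} ({formula['C']} C available)"
        )
    if label.nD > formula["H"]:
        raise LabelOverflowError(
            f"cannot place {label.nD} x D in {formula} ({formula['H']} H available)"
        )
    counts = dict(formula.counts)
    if label.n13C:
        counts["C"] = counts.get("C", 0) - label.n13C
        counts["13C"] = counts.get("13C", 0) + label.n13C
    if label.nD:
        counts["H"] = counts.get("H", 0) - label.nD
        counts["D"] = counts.get("D", 0) + label.nD
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Sum of per-isotope principal masses from the module mass table, in Da."""
    return float(sum(ISOTOPE_MASS[sym] * n for sym, n in formula.counts.items()))


def adduct_mz(neutral_mass: float, adduct: Adduct) -> float:
    """m/z of the singly charged [M+X]+ cation (electron mass subtracted)."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be >= 0")
    return neutral_mass + adduct.mass_delta


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed parts-per-million error, (obs - theo)/theo * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def isotopologue_envelope(
    formula: ElementalFormula, n_peaks: int = 3
) -> list[tuple[float, float]]:
    """Natural-abundance aggregated isotopologue envelope M+0 ... M+(n_peaks-1).

    Returns ``(mass offset from M+0 in Da, abundance relative to M+0)`` pairs.
    Computed by element-wise polynomial convolution over neutron-shift space;
    within each aggregated peak the mass offset is the abundance-weighted mean.
    Atoms already substituted by a label (13C, D) are treated as pure isotopes
    and contribute no further envelope.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    # state: prob[k] and first-moment mom[k] = sum(prob * mass shift) per shift k
    prob = np.zeros(n_peaks)
    mom = np.zeros(n_peaks)
    prob[0] = 1.0

    for sym, n_atoms in formula.counts.items():
        pattern = _NATURAL_PATTERN[sym]
        if len(pattern) == 1 or n_atoms == 0:
            continue
        a_prob = np.zeros(n_peaks)
        a_mom = np.zeros(n_peaks)
        for shift, p, dm in pattern:
            if shift < n_peaks:
                a_prob[shift] += p
                a_mom[shift] += p * dm
        # raise the single-atom pattern to the n_atoms-th power (binary exp.)
        e_prob, e_mom = np.zeros(n_peaks), np.zeros(n_peaks)
        e_prob[0] = 1.0
        b_prob, b_mom = a_prob, a_mom
        n = n_atoms
        while n:
            if n & 1:
                e_prob, e_mom = _convolve_moments(e_prob, e_mom, b_prob, b_mom)
            n >>= 1
            if n:
                b_prob, b_mom = _convolve_moments(b_prob, b_mom, b_prob, b_mom)
        prob, mom = _convolve_moments(prob, mom, e_prob, e_mom)

    if prob[0] <= 0:
        raise ValueError("degenerate envelope: zero monoisotopic abundance")
    out: list[tuple[float, float]] = []
    for k in range(n_peaks):
        if prob[k] > 0:
            out.append((mom[k] / prob[k], prob[k] / prob[0]))
        else:
            out.append((float(k) * MASS_13C_SHIFT, 0.0))
    return out


def _convolve_moments(
    p1: np.ndarray, m1: np.ndarray, p2: np.ndarray, m2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated convolution of (probability, first-moment) pairs."""
    n = len(p1)
    p = np.convolve(p1, p2)[:n]
    # moment of a sum: E[m] distributes as p1*m2 + m1*p2
    m = (np.convolve(p1, m2) + np.convolve(m1, p2))[:n]
    return p, m


def resolving_power_required(mz_a: float, mz_b: float) -> float:
    """FWHM resolving power needed to separate two ions: mean(m/z)/|delta|."""
    if mz_a == mz_b:
        raise ValueError("ions with identical m/z cannot be resolved")
    return 0.5 * (mz_a + mz_b) / abs(mz_a - mz_b)
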