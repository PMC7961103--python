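"""Label-aware prediction of PC MS/MS fragments and spectrum annotation.

Sodiated and potassiated PC precursors fragment by two diagnostic headgroup
neutral losses: trimethylamine (C3H9N, nominal 59) and the phosphocholine
headgroup (C5H14NO4P, nominal 183).  Protonated precursors instead yield the
phosphocholine cation at nominal m/z 184.  Isotope labels shift these
signatures in a tracer-specific way — the D9-choline label (nine deuteriums
on the N-methyls) departs entirely with either loss, a 13C5-choline headgroup
routes three 13C into trimethylamine and five into phosphocholine, and the
13C24 re-acylation label does the same while retaining its sixteen palmitoyl
13C (plus three glycerol 13C) on the fragment.  These routings make labeled
losses of nominal 62/68 and 188/192 the unambiguous fingerprints of a
labeled headgroup.

Fragment names follow the Pauling-style shorthand used for PC neutral
losses, e.g. ``-PC(59)`` and the labeled ``-PC(+[13]C3(62)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mass import (
    ELECTRON_MASS,
    ISOTOPE_MASS,
    Adduct,
    ElementalFormula,
    LabelSpec,
    LipidSpecies,
    adduct_mz,
    apply_label,
    monoisotopic_mass,
    ppm_error,
)
from .msio import Spectrum

__all__ = [
    "FragmentPrediction",
    "FragmentRouting",
    "LABEL_ROUTING",
    "predict_pc_fragments",
    "annotate_msms",
]

TRIMETHYLAMINE = ElementalFormula({"C": 3, "H": 9, "N": 1})  # nominal 59
PHOSPHOCHOLINE_LOSS = ElementalFormula({"C": 5, "H": 14, "N": 1, "O": 4, "P": 1})  # 183
PROTON_MASS = ISOTOPE_MASS["H"] - ELECTRON_MASS


@dataclass(frozen=True)
class FragmentRouting:
    """How many labeled atoms depart with each headgroup loss.

    The phosphocholine routing also covers the protonated-precursor headgroup
    cation (same five carbons and fourteen hydrogens plus the ionizing proton).
    """

    tma_13C: int = 0
    tma_D: int = 0
    pchol_13C: int = 0
    pchol_D: int = 0


#: Routing per known tracer.  D9-choline deuteriums all sit on the three
#: N-methyls; every 13C tracer in scope carries a fully labeled choline
#: (3 methyl C into trimethylamine, 5 C into phosphocholine).
LABEL_ROUTING: dict[str, FragmentRouting] = {
    "": FragmentRouting(),
    "D9": FragmentRouting(tma_D=9, pchol_D=9),
    "13C5": FragmentRouting(tma_13C=3, pchol_13C=5),
    "13C24": FragmentRouting(tma_13C=3, pchol_13C=5),
    "U13C": FragmentRouting(tma_13C=3, pchol_13C=5),
}


@dataclass(frozen=True)
class FragmentPrediction:
    """A predicted MS/MS fragment of a PC precursor ion."""

    name: str
    neutral_loss_formula: ElementalFormula | None
    neutral_loss_nominal: int
    fragment_mz: float
    carries_label: bool
    precursor_mz: float

    @property
    def neutral_loss_mass(self) -> float:
        if self.neutral_loss_formula is None:
            return self.precursor_mz - self.fragment_mz
        return monoisotopic_mass(self.neutral_loss_formula)


def _loss_name(base_nominal: int, labeled_nominal: int, routing_13C: int, routing_D: int) -> str:
    if routing_13C:
        return f"-PC(+[13]C{routing_13C}({labeled_nominal})"
    if routing_D:
        return f"-PC(+D{routing_D}({labeled_nominal})"
    return f"-PC({base_nominal})"


def predict_pc_fragments(
    species: LipidSpecies,
    adduct: Adduct,
    routing: FragmentRouting | None = None,
) -> list[FragmentPrediction]:
    """Predict the diagnostic headgroup fragments of a PC precursor ion.

    Sodiated/potassiated precursors give the trimethylamine and
    phosphocholine neutral-loss fragments; protonated precursors give the
    phosphocholine headgroup cation (nominal 184, shifted to 193 by D9 and
    189 by a 13C5 headgroup).  ``routing`` overrides the per-tracer table in
    :data:`LABEL_ROUTING`; it must be supplied for labels with unknown names.
    """
    label = species.label
    if routing is None:
        if label.name not in LABEL_ROUTING and not label.is_unlabeled:
            raise ValueError(
                f"no fragment routing known for label {label.name!r}; "
                "pass an explicit FragmentRouting"
            )
        routing = LABEL_ROUTING.get(label.name, FragmentRouting())
    if routing.tma_13C > label.n13C or routing.pchol_13C > label.n13C:
        raise ValueError("routing sends more 13C into a loss than the label holds")
    if routing.tma_D > label.nD or routing.pchol_D > label.nD:
        raise ValueError("routing sends more D into a loss than the label holds")

    precursor_mz = species.mz(adduct)
    out: list[FragmentPrediction] = []

    if adduct.kind in ("Na", "K"):
        for base, base_nominal, r13, rD in (
            (TRIMETHYLAMINE, 59, routing.tma_13C, routing.tma_D),
            (PHOSPHOCHOLINE_LOSS, 183, routing.pchol_13C, routing.pchol_D),
        ):
            loss = apply_label(base, LabelSpec(r13, rD, label.name))
            loss_mass = monoisotopic_mass(loss)
            nominal = round(loss_mass)
            out.append(
                FragmentPrediction(
                    name=_loss_name(base_nominal, nominal, r13, rD),
                    neutral_loss_formula=loss,
                    neutral_loss_nominal=nominal,
                    fragment_mz=precursor_mz - loss_mass,
                    carries_label=bool(r13 or rD),
                    precursor_mz=precursor_mz,
                )
            )
    elif adduct.kind == "H":
        # phosphocholine cation C5H15NO4P+ (headgroup + ionizing proton)
        cation = apply_label(
            PHOSPHOCHOLINE_LOSS, LabelSpec(routing.pchol_13C, routing.pchol_D, label.name)
        )
        cation_mz = monoisotopic_mass(cation) + PROTON_MASS
        nominal = round(cation_mz)
        out.append(
            FragmentPrediction(
                name=f"PC headgroup({nominal})",
                neutral_loss_formula=None,
                neutral_loss_nominal=nominal,
                fragment_mz=cation_mz,
                carries_label=bool(routing.pchol_13C or routing.pchol_D),
                precursor_mz=precursor_mz,
            )
        )
    else:  # pragma: no cover - Adduct already restricts kinds
        raise ValueError(f"unsupported adduct {adduct}")
    return out


def annotate_msms(
    spectrum: Spectrum,
    predictions: list[FragmentPrediction],
    tol_ppm: float = 5.0,
) -> tuple[list[tuple[FragmentPrediction, float, float]], list[FragmentPrediction]]:
    """Match predictions to a centroid MS/MS spectrum within a closed ppm window.

    For each prediction, the most intense peak within +-``tol_ppm`` is taken
    as the observation and its signed ppm error reported.  Returns
    ``(matches, unmatched)`` where matches are
    ``(prediction, observed m/z, ppm error)``.
    """
    matches: list[tuple[FragmentPrediction, float, float]] = []
    unmatched: list[FragmentPrediction] = []
    for pred in predictions:
        half = pred.fragment_mz * tol_ppm * 1e-6
        lo = np.searchsorted(spectrum.mz, pred.fragment_mz - half, side="left")
        hi = np.searchsorted(spectrum.mz, pred.fragment_mz + half, side="right")
        if hi <= lo:
            unmatched.append(pred)
            continue
        best = lo + int(np.argmax(spectrum.intensities[lo:hi]))
        obs = float(spectrum.mz[best])
        matches.append((pred, obs, ppm_error(obs, pred.fragment_mz)))
    return matches, unmatched
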