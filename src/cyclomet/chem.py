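"""Accurate-mass arithmetic for natural-product dereplication.

Molecular formulas, monoisotopic masses, adduct m/z, ppm errors,
ring-plus-double-bond equivalents (RDBE), and matching of observed ions
against a bundled accurate-mass/retention-time library of known and new
fungal secondary metabolites (polyketides, cytochalasins and cyclic
nonribosomal pentapeptides).

All masses are monoisotopic (most abundant isotope) in daltons. Only
singly charged positive-mode adducts ([M+H]+ and [M+Na]+) are modeled.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "rdbe",
    "ppm_error",
    "LibraryEntry",
    "load_library",
    "dereplicate",
]

#: Monoisotopic mass of the most abundant isotope, Da (CODATA/NIST scale).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "F": 18.99840322,
    "K": 38.96370668,
    "Br": 78.9183371,
    "I": 126.904473,
}

PROTON_MASS = 1.007276
ELECTRON_MASS = 0.000549

# Halogens count like hydrogen in the RDBE formula; O, S and monovalent
# metals (Na, K) contribute nothing.
_RDBE_LIKE_H = ("H", "Cl", "F", "Br", "I")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map with Hill-order canonical rendering.

    Counts are strictly positive; elements must be present in
    :data:`MONOISOTOPIC_MASS`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {el} must be a positive integer, got {n!r}")
            clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise FormulaError(f"cannot remove {n} {el} from {self}")
            if left == 0:
                merged.pop(el)
            else:
                merged[el] = left
        return MolecularFormula(merged)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __str__(self) -> str:
        # Hill order: C first, H second, then remaining symbols alphabetically.
        order = []
        if "C" in self.counts:
            order.append("C")
            if "H" in self.counts:
                order.append("H")
            order.extend(sorted(el for el in self.counts if el not in ("C", "H")))
        else:
            order.extend(sorted(self.counts))
        return "".join(f"{el}{self.counts[el] if self.counts[el] > 1 else ''}" for el in order)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``"C17H18ClO6"`` into a :class:`MolecularFormula`.

    No parentheses, isotope labels or charge signs are supported.
    Repeated element symbols accumulate. A written count of zero is an
    error, as is any symbol absent from the bundled mass table.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    counts: dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    while pos < len(stripped):
        m = _TOKEN.match(stripped, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"cannot parse formula {text!r} at {stripped[pos:]!r}")
        el, digits = m.groups()
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula | Mapping[str, int] | str) -> float:
    """Sum of monoisotopic element masses, Da. Additive over formulas."""
    if isinstance(f, str):
        f = parse_formula(f)
    counts = f.counts if isinstance(f, MolecularFormula) else f
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items()))


#: adduct name -> mass added to the neutral monoisotopic mass
ADDUCT_SHIFT = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS,
}


def ion_mz(neutral: MolecularFormula | str, adduct: str = "[M+H]+") -> float:
    """m/z of a singly charged positive adduct of a neutral formula.

    Equivalent (to <1e-6 Da) to the mass of the ion formula (neutral plus
    the adduct atom) minus one electron.
    """
    if adduct not in ADDUCT_SHIFT:
        raise ValueError(f"unsupported adduct {adduct!r}; known: {sorted(ADDUCT_SHIFT)}")
    return monoisotopic_mass(neutral) + ADDUCT_SHIFT[adduct]


def rdbe(f: MolecularFormula | str) -> float:
    """Ring-plus-double-bond equivalents: C + 1 + N/2 - (H + halogens)/2.

    O, S, Na and K contribute zero. May be half-integral for ion
    (protonated) formulas; integral for neutral even-electron molecules.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    h_like = sum(f[el] for el in _RDBE_LIKE_H)
    return f["C"] + 1.0 + f["N"] / 2.0 - h_like / 2.0


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error, parts per million.

    Convention: ``(theoretical - measured) / measured * 1e6``, so an ion
    measured heavier than calculated has a negative error.
    """
    if measured <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return (theoretical - measured) / measured * 1e6


@dataclass(frozen=True)
class LibraryEntry:
    """One row of the bundled accurate-mass/RT compound library."""

    name: str
    compound_class: str  # PKS | NRPS | PKS-NRPS
    rt_min: float
    ion_formula: str  # as printed; a trailing Na marks a sodiated ion
    measured_mz: float
    calc_mz: float  # calculated m/z as printed in the source table
    ppm_printed: float  # ppm error as printed in the source table

    @property
    def adduct(self) -> str:
        return "[M+Na]+" if self.ion_formula.endswith("Na") else "[M+H]+"

    @property
    def neutral_formula(self) -> MolecularFormula:
        ion = parse_formula(self.ion_formula)
        return ion - parse_formula("Na" if self.adduct == "[M+Na]+" else "H")

    @property
    def recomputed_mz(self) -> float:
        """Calculated m/z recomputed from the ion formula (ion mass − e⁻)."""
        return monoisotopic_mass(self.ion_formula) - ELECTRON_MASS

    @property
    def mass_consistent(self) -> bool:
        """True when the printed calculated m/z agrees with the formula.

        One bundled entry (epoxycytochalasin D) carries a printed
        calculated mass that is 0.0018 Da away from the value implied by
        its own ion formula; the flag exposes such internal typos rather
        than silently repairing them.
        """
        return abs(self.recomputed_mz - self.calc_mz) <= 5e-4


def load_library() -> list[LibraryEntry]:
    """Load the bundled 19-compound library (knowns 1-11, new 12-19)."""
    ref = resources.files("cyclomet.data").joinpath("known_compounds.csv")
    with ref.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return [
        LibraryEntry(
            name=r["name"],
            compound_class=r["compound_class"],
            rt_min=float(r["rt_min"]),
            ion_formula=r["ion_formula"],
            measured_mz=float(r["measured_mz"]),
            calc_mz=float(r["calc_mz"]),
            ppm_printed=float(r["ppm_printed"]),
        )
        for r in rows
    ]


@dataclass(frozen=True)
class DereplicationHit:
    entry: LibraryEntry
    ppm: float
    delta_rt: float


def dereplicate(
    observed_mz: float,
    observed_rt: float,
    tol_ppm: float = 5.0,
    tol_rt: float = 0.5,
    library: Iterable[LibraryEntry] | None = None,
) -> list[DereplicationHit]:
    """Match an observed accurate mass + RT against the compound library.

    Returns entries with |ppm error| <= tol_ppm (against the library's
    calculated m/z) and |RT difference| <= tol_rt minutes, sorted by
    |ppm| ascending, ties broken by RT difference then name.
    """
    if tol_ppm <= 0 or tol_rt <= 0:
        raise ValueError("tolerances must be positive")
    if library is None:
        library = load_library()
    hits = []
    for entry in library:
        ppm = ppm_error(observed_mz, entry.calc_mz)
        drt = abs(observed_rt - entry.rt_min)
        if abs(ppm) <= tol_ppm and drt <= tol_rt:
            hits.append(DereplicationHit(entry=entry, ppm=ppm, delta_rt=drt))
    hits.sort(key=lambda h: (abs(h.ppm), h.delta_rt, h.entry.name))
    return hits
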