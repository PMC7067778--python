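"""Cyclic peptides, ring openings and b-ion fragmentation.

Cyclic nonribosomal peptides fragment in positive-mode CID by
ring-opening: protonation and cleavage of one amide bond produces a
linear acylium ion whose sequential losses give a b-ion ladder. Each of
the n amide bonds is a potential opening, so a cyclic n-peptide has n
ladders; the full-length b ion (bn) is common to all of them and equals
the precursor [M+H]+ (no water is gained on ring opening).

Only b ions are modeled: the diagnostic ladders of proline-containing
cyclopentapeptides are interpreted this way throughout, and y ions,
neutral losses and immonium ions are deliberately out of scope (an
extension can subclass :func:`b_series`).

Leucine and isoleucine are isobaric (residue mass 113.08406 Da); MS
cannot tell them apart, so both carry the collapsed class label ``Xle``
used when comparing sequences. D/L stereochemistry is likewise invisible
to MS and is not modeled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chem import PROTON_MASS, MolecularFormula, monoisotopic_mass, parse_formula
from .spectra import MsMsSpectrum

__all__ = [
    "Residue",
    "default_alphabet",
    "get_residue",
    "CyclicPeptide",
    "b_series",
    "cyclospectrum",
    "FragmentAnnotation",
    "annotate_spectrum",
]


@dataclass(frozen=True)
class Residue:
    """An amino-acid residue (the amino acid minus water)."""

    name: str
    composition: MolecularFormula
    n_methylated: bool = False
    isobaric_class: str | None = None

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.composition)

    @property
    def label(self) -> str:
        """Name collapsed over mass-indistinguishable residues."""
        return self.isobaric_class or self.name


# Residue compositions (amino acid minus H2O).
_RESIDUE_COMPOSITIONS = {
    "Gly": "C2H3NO",
    "Ala": "C3H5NO",
    "Ser": "C3H5NO2",
    "Pro": "C5H7NO",
    "Val": "C5H9NO",
    "Thr": "C4H7NO2",
    "Cys": "C3H5NOS",
    "Leu": "C6H11NO",
    "Ile": "C6H11NO",
    "Asn": "C4H6N2O2",
    "Asp": "C4H5NO3",
    "Gln": "C5H8N2O2",
    "Lys": "C6H12N2O",
    "Glu": "C5H7NO3",
    "Met": "C5H9NOS",
    "His": "C6H7N3O",
    "Phe": "C9H9NO",
    "Arg": "C6H12N4O",
    "Tyr": "C9H9NO2",
    "Trp": "C11H10N2O",
    # N-methyl-phenylalanine: Phe + CH2, common in fungal NRPS products.
    "NMePhe": "C10H11NO",
}

_ALIASES = {"IsoLeu": "Ile", "N-MePhe": "NMePhe", "NMe-Phe": "NMePhe"}


def default_alphabet() -> list[Residue]:
    """The 20 proteinogenic residues plus N-methyl-phenylalanine."""
    out = []
    for name, comp in _RESIDUE_COMPOSITIONS.items():
        out.append(
            Residue(
                name=name,
                composition=parse_formula(comp),
                n_methylated=name.startswith("NMe"),
                isobaric_class="Xle" if name in ("Leu", "Ile") else None,
            )
        )
    return out


_BY_NAME = {r.name: r for r in default_alphabet()}


def get_residue(name: str) -> Residue:
    key = _ALIASES.get(name, name)
    try:
        return _BY_NAME[key]
    except KeyError:
        raise KeyError(f"unknown residue name {name!r}") from None


_CYCLO = re.compile(r"^cyclo[-\(\[]?(.*?)[\)\]]?$", re.IGNORECASE)


class CyclicPeptide:
    """An ordered residue ring, N->C; rotations denote the same molecule."""

    def __init__(self, residues: Sequence[Residue | str]):
        res = tuple(get_residue(r) if isinstance(r, str) else r for r in residues)
        if len(res) < 2:
            raise ValueError("a cyclic peptide needs at least 2 residues")
        self.residues = res

    @classmethod
    def from_string(cls, text: str) -> "CyclicPeptide":
        """Parse ``"cyclo(NMePhe-Ala-Ile-Leu-Pro)"`` (the cyclo() wrapper is optional)."""
        m = _CYCLO.match(text.strip())
        inner = m.group(1) if m else text.strip()
        return cls([tok.strip() for tok in inner.split("-") if tok.strip()])

    def __len__(self) -> int:
        return len(self.residues)

    def __repr__(self) -> str:
        return f"cyclo({'-'.join(r.name for r in self.residues)})"

    def __eq__(self, other) -> bool:
        return isinstance(other, CyclicPeptide) and self.rotation_key() == other.rotation_key()

    def __hash__(self) -> int:
        return hash(self.rotation_key())

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic neutral mass: sum of residue masses (head-to-tail
        cyclization removes the water of the linear peptide)."""
        return float(sum(r.mass for r in self.residues))

    @property
    def formula(self) -> MolecularFormula:
        total = self.residues[0].composition
        for r in self.residues[1:]:
            total = total + r.composition
        return total

    @property
    def precursor_mz(self) -> float:
        """m/z of the singly protonated molecule [M+H]+."""
        return self.neutral_mass + PROTON_MASS

    def reversed(self) -> "CyclicPeptide":
        """The mirror ring (C->N reading). A ring and its mirror share the
        same contiguous-run mass sums, hence identical cyclospectra: b-ion
        masses alone cannot determine the reading direction of a cycle."""
        return CyclicPeptide(self.residues[::-1])

    def rotations(self) -> list[tuple[Residue, ...]]:
        n = len(self.residues)
        return [self.residues[i:] + self.residues[:i] for i in range(n)]

    def ring_openings(self) -> list[tuple[str, tuple[Residue, ...]]]:
        """All n ring-opened linear sequences with their cleaved-bond labels.

        Opening the amide bond preceding residue i yields the rotation
        that starts at residue i; the label names the cleaved bond as
        ``"prev-next"`` (e.g. ``"Pro-NMePhe"`` for the opening that puts
        NMePhe at the N-terminus).
        """
        n = len(self.residues)
        out = []
        for i in range(n):
            label = f"{self.residues[i - 1].name}-{self.residues[i].name}"
            out.append((label, self.residues[i:] + self.residues[:i]))
        return out

    def rotation_key(self, collapse_isobaric: bool = False) -> tuple[str, ...]:
        """Canonical ring identity: the lexicographically smallest rotation
        of the residue-name list (N->C direction fixed; no reflection).

        With ``collapse_isobaric`` Leu/Ile are merged into ``Xle``.
        """
        names = [r.label if collapse_isobaric else r.name for r in self.residues]
        n = len(names)
        return min(tuple(names[i:] + names[:i]) for i in range(n))


def b_series(linear: Sequence[Residue | str]) -> np.ndarray:
    """b-ion m/z ladder b1..bn of a linear (ring-opened acylium) sequence.

    b_k = sum of the first k residue masses + proton. For a ring-opened
    cyclic peptide, bn equals the precursor [M+H]+.
    """
    res = [get_residue(r) if isinstance(r, str) else r for r in linear]
    if not res:
        raise ValueError("empty residue sequence")
    masses = np.array([r.mass for r in res])
    return np.cumsum(masses) + PROTON_MASS


def cyclospectrum(p: CyclicPeptide, dedup: bool = False) -> np.ndarray:
    """All theoretical b ions over every ring opening, sorted ascending.

    The multiset holds n(n-1) proper-prefix ions plus the single shared
    full-length ion (= precursor m/z). With ``dedup``, values equal to
    1e-6 Da are reported once (symmetric rings collapse heavily).
    """
    ions = []
    for _, linear in p.ring_openings():
        ions.extend(b_series(linear)[:-1])
    ions.append(p.precursor_mz)
    arr = np.sort(np.asarray(ions))
    if dedup:
        arr = np.unique(np.round(arr, 6))
    return arr


@dataclass(frozen=True)
class FragmentAnnotation:
    """A theoretical b ion matched (or not) against an observed peak."""

    opening: str  # cleaved bond, e.g. "Pro-NMePhe"
    ordinal: int  # 1-based: b1..bn
    residue_lost_next: str | None  # residue whose loss produces this ion from b(k+1)
    theoretical_mz: float
    observed_mz: float | None
    delta: float | None


def annotate_spectrum(
    p: CyclicPeptide, spectrum: MsMsSpectrum, tol: float = 0.02
) -> tuple[list[FragmentAnnotation], dict[str, float]]:
    """Match every theoretical b ion of every ring opening to the spectrum.

    Each theoretical ion is matched to the nearest observed peak within
    ``tol`` Da (one observed peak may explain several theoretical ions).
    Returns the annotations and per-opening coverage, where coverage is
    the matched fraction of the n-1 proper-prefix ions of that opening
    (bn is shared by all openings and excluded from coverage).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    n = len(p)
    annotations: list[FragmentAnnotation] = []
    coverage: dict[str, float] = {}
    obs = spectrum.mz
    for label, linear in p.ring_openings():
        ladder = b_series(linear)
        matched = 0
        for k, theo in enumerate(ladder, start=1):
            observed = delta = None
            if obs.size:
                j = int(np.argmin(np.abs(obs - theo)))
                if abs(obs[j] - theo) <= tol:
                    observed = float(obs[j])
                    delta = float(obs[j] - theo)
                    if k < n:
                        matched += 1
            annotations.append(
                FragmentAnnotation(
                    opening=label,
                    ordinal=k,
                    # b_k arises from b_{k+1} by loss of residue k+1 (bn loses none).
                    residue_lost_next=linear[k].name if k < n else None,
                    theoretical_mz=float(theo),
                    observed_mz=observed,
                    delta=delta,
                )
            )
        coverage[label] = matched / (n - 1) if n > 1 else 0.0
    return annotations, coverage
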