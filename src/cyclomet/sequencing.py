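"""De novo sequencing of cyclic peptides from b-ion fragment ladders.

A branch-and-bound search grows linear prefixes whose b ions all lie
within tolerance of observed peaks (up to a configurable mismatch
budget, to survive peak dropout), and closes the ring only when the
residue-mass total plus a proton matches the precursor. Candidates are
reported once per rotation class; because Leu and Ile are isobaric the
default report collapses them to the Xle class.

Two degeneracies are inherent to mass-only sequencing and are not
resolved here: Leu/Ile (equal residue mass) and ring reflection — the
theoretical b ions over all openings are the sums of contiguous runs of
the ring, a set invariant under reversing the ring, so a non-palindromic
true ring and its mirror always tie on a noiseless spectrum and both are
reported (as distinct rotation classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import PROTON_MASS
from .peptides import CyclicPeptide, Residue, cyclospectrum, default_alphabet
from .spectra import MsMsSpectrum

__all__ = ["SequencingCandidate", "sequence_candidates", "enumerate_rings"]


@dataclass(frozen=True)
class SequencingCandidate:
    peptide: CyclicPeptide
    matched_peaks: int  # observed peaks explained by the candidate cyclospectrum
    coverage: float  # matched_peaks / number of observed peaks
    precursor_delta: float
    rotation_key: tuple[str, ...]


def _score(p: CyclicPeptide, obs_mz: np.ndarray, tol: float) -> int:
    """Number of observed peaks within tol of some theoretical b ion."""
    theo = cyclospectrum(p, dedup=True)
    if obs_mz.size == 0 or theo.size == 0:
        return 0
    idx = np.searchsorted(theo, obs_mz)
    left = np.abs(obs_mz - theo[np.clip(idx - 1, 0, theo.size - 1)])
    right = np.abs(obs_mz - theo[np.clip(idx, 0, theo.size - 1)])
    return int(np.sum(np.minimum(left, right) <= tol))


def sequence_candidates(
    precursor_mz: float,
    spectrum: MsMsSpectrum,
    alphabet: Sequence[Residue] | None = None,
    ring_size: int = 5,
    tol: float = 0.02,
    keep: int = 10,
    max_mismatches: int = 0,
    collapse_isobaric: bool = True,
) -> list[SequencingCandidate]:
    """Search rings of ``ring_size`` residues consistent with the spectrum.

    A prefix is extended only while each of its b ions is within ``tol``
    of an observed peak, allowing at most ``max_mismatches`` unmatched
    prefix ions along the way (raise the budget for sparse spectra).
    The ring closes when |sum of residues + proton - precursor| <= tol.
    Output is deduplicated by rotation class (Leu/Ile collapsed when
    ``collapse_isobaric``), ranked by matched-peak count, then smaller
    precursor delta, then canonical key; at most ``keep`` candidates.
    """
    if ring_size < 2:
        raise ValueError("ring_size must be >= 2")
    if keep < 1:
        raise ValueError("keep must be >= 1")
    alphabet = list(alphabet) if alphabet is not None else default_alphabet()
    if not alphabet:
        raise ValueError("alphabet must not be empty")
    if collapse_isobaric:
        # One residue per mass-indistinguishable class keeps the search
        # from enumerating Leu/Ile permutations it cannot rank.
        seen: dict[str, Residue] = {}
        for r in alphabet:
            seen.setdefault(r.label, r)
        alphabet = list(seen.values())

    obs = np.asarray(spectrum.mz, dtype=float)
    masses = np.array([r.mass for r in alphabet])
    min_mass, max_mass = float(masses.min()), float(masses.max())
    target = precursor_mz - PROTON_MASS  # total residue mass of the ring

    def near_peak(mz: float) -> bool:
        if obs.size == 0:
            return False
        j = np.searchsorted(obs, mz)
        for k in (j - 1, j):
            if 0 <= k < obs.size and abs(obs[k] - mz) <= tol:
                return True
        return False

    best: dict[tuple[str, ...], CyclicPeptide] = {}

    def extend(prefix: list[Residue], mass: float, misses: int) -> None:
        depth = len(prefix)
        remaining = ring_size - depth
        if remaining == 0:
            if abs(mass - target) <= tol:
                cand = CyclicPeptide(prefix)
                best.setdefault(cand.rotation_key(collapse_isobaric), cand)
            return
        # mass-window prune: the remaining residues must be able to reach target
        lo = mass + remaining * min_mass
        hi = mass + remaining * max_mass
        if lo - tol > target or hi + tol < target:
            return
        for r, m in zip(alphabet, masses):
            new_mass = mass + m
            if new_mass - target > tol:
                continue
            is_last = remaining == 1
            if is_last:
                # the closing b ion is the precursor itself; only the mass gate applies
                extend(prefix + [r], new_mass, misses)
            else:
                hit = near_peak(new_mass + PROTON_MASS)
                new_misses = misses + (0 if hit else 1)
                if new_misses <= max_mismatches:
                    extend(prefix + [r], new_mass, new_misses)

    extend([], 0.0, 0)

    candidates = []
    for key, pep in best.items():
        matched = _score(pep, obs, tol)
        candidates.append(
            SequencingCandidate(
                peptide=pep,
                matched_peaks=matched,
                coverage=matched / obs.size if obs.size else 0.0,
                precursor_delta=float(pep.precursor_mz - precursor_mz),
                rotation_key=key,
            )
        )
    candidates.sort(key=lambda c: (-c.matched_peaks, abs(c.precursor_delta), c.rotation_key))
    return candidates[:keep]


def enumerate_rings(
    precursor_mz: float,
    spectrum: MsMsSpectrum,
    alphabet: Sequence[Residue],
    ring_size: int,
    tol: float = 0.02,
    collapse_isobaric: bool = True,
) -> list[tuple[str, ...]]:
    """Exhaustive reference enumeration of every alphabet^n ring that is
    spectrum-consistent: the precursor matches and at least one ring
    opening has every proper-prefix b ion within tol of an observed
    peak. One rotation class each, sorted. Exponential: use only for
    small alphabets/rings (oracle for the branch-and-bound search).
    """
    from itertools import product

    obs = np.asarray(spectrum.mz, dtype=float)

    def ladder_ok(linear) -> bool:
        total = 0.0
        for r in linear[:-1]:
            total += r.mass
            if obs.size == 0 or np.min(np.abs(obs - (total + PROTON_MASS))) > tol:
                return False
        return True

    found: dict[tuple[str, ...], None] = {}
    for combo in product(alphabet, repeat=ring_size):
        pep = CyclicPeptide(combo)
        if abs(pep.precursor_mz - precursor_mz) > tol:
            continue
        if any(ladder_ok(rot) for rot in pep.rotations()):
            found.setdefault(pep.rotation_key(collapse_isobaric), None)
    return sorted(found)
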