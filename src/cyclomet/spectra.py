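"""Tandem-MS peak lists: container plus MGF / two-column text I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["MsMsSpectrum", "read_mgf", "read_two_column", "write_mgf"]


@dataclass(frozen=True)
class MsMsSpectrum:
    """An MS/MS spectrum: precursor m/z and (m/z, intensity) peaks.

    Peaks are kept sorted by m/z; intensities are non-negative.
    """

    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    title: str = ""

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity must have equal length")
        if mz.size and mz.min() <= 0:
            raise ValueError("peak m/z values must be positive")
        if inten.size and inten.min() < 0:
            raise ValueError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_peaks(cls, precursor_mz, peaks, title=""):
        peaks = list(peaks)
        mz = [p[0] for p in peaks]
        inten = [p[1] for p in peaks]
        return cls(precursor_mz=precursor_mz, mz=np.array(mz), intensity=np.array(inten), title=title)


def read_mgf(path: str | Path) -> list[MsMsSpectrum]:
    """Read all spectra from an MGF peak-list file."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            out.append(
                MsMsSpectrum(
                    precursor_mz=precursor,
                    mz=np.asarray(spec["m/z array"], dtype=float),
                    intensity=np.asarray(spec["intensity array"], dtype=float),
                    title=str(params.get("title", "")),
                )
            )
    return out


def read_two_column(path: str | Path, precursor_mz: float) -> MsMsSpectrum:
    """Read a plain whitespace-delimited ``m/z intensity`` peak list."""
    mz, inten = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        mz.append(float(parts[0]))
        inten.append(float(parts[1]) if len(parts) > 1 else 1.0)
    return MsMsSpectrum(precursor_mz=precursor_mz, mz=np.array(mz), intensity=np.array(inten))


def write_mgf(spectra: list[MsMsSpectrum] | MsMsSpectrum, path: str | Path) -> None:
    if isinstance(spectra, MsMsSpectrum):
        spectra = [spectra]
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {"title": s.title or f"spectrum_{i}", "pepmass": s.precursor_mz, "charge": "1+"},
        }
        for i, s in enumerate(spectra)
    ]
    _mgf.write(entries, str(path), file_mode="w")
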