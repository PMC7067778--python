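"""Synthetic LC-MS study generator and MS/MS spectrum simulator.

Emulates the design of the endophyte metabolomics study: 15 fungal
strains (4 from cultivated highbush blueberry, 11 from wild blueberry)
grown on two media (ML, PDB), with filtrate and mycelium extracts per
culture — 60 samples — and 3,856 aligned LC-MS features. Integrated
areas are log-normal; a small disjoint set of planted marker features
per contrast carries a log-scale group shift, providing ground truth
for prioritization benchmarks. Acquisition constants mirror the study:
m/z uniform on [150, 1100], retention time uniform on [0, 31] min.

The generator does not emulate chromatographic peak shapes, isotope
envelopes, adduct correlation structure or missingness, so recovery
results here speak to the statistics, not to peak-picking quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable
from .peptides import CyclicPeptide, cyclospectrum
from .spectra import MsMsSpectrum

__all__ = ["StudyDesign", "GroundTruth", "simulate_study", "simulate_msms"]

#: the pairwise comparisons run in the study
CONTRASTS = ("medium", "host")


@dataclass(frozen=True)
class StudyDesign:
    """Study layout and statistical structure of the simulated tables."""

    n_strains_highbush: int = 4
    n_strains_wild: int = 11
    media: tuple[str, ...] = ("ML", "PDB")
    matrices: tuple[str, ...] = ("filtrate", "mycelium")
    n_features: int = 3856
    n_markers: int = 30  # planted markers per contrast (disjoint sets)
    effect_size: float = 3.0  # log-scale shift in units of the noise sd
    log_mean: float = 12.5  # mean of per-feature baseline log-areas
    log_mean_sd: float = 2.0  # spread of baselines across features
    log_noise_sd: float = 1.0  # within-group biological + technical noise
    area_ceiling: float = 1e9
    isotope_fraction: float = 0.05
    mz_range: tuple[float, float] = (150.0, 1100.0)  # acquisition scan range
    rt_range: tuple[float, float] = (0.0, 31.0)  # gradient length, min

    @property
    def n_strains(self) -> int:
        return self.n_strains_highbush + self.n_strains_wild

    @property
    def n_samples(self) -> int:
        return self.n_strains * len(self.media) * len(self.matrices)


@dataclass(frozen=True)
class GroundTruth:
    """Planted marker features per contrast with effect directions (±1)."""

    markers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def ids(self, contrast: str) -> list[str]:
        return list(self.markers[contrast].index)


def simulate_study(design: StudyDesign = StudyDesign(), seed: int = 0) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table plus ground truth, reproducibly from seed.

    Markers for the ``medium`` contrast shift ML samples, markers for
    the ``host`` contrast shift highbush samples, each by
    ``effect_size * log_noise_sd`` on the log scale in a random
    direction per feature. Marker sets are disjoint.
    """
    d = design
    total_markers = d.n_markers * len(CONTRASTS)
    if total_markers > d.n_features:
        raise ValueError("more planted markers than features")
    rng = np.random.default_rng(seed)

    # sample metadata
    strains = [f"HB{i + 1:02d}" for i in range(d.n_strains_highbush)] + [
        f"WB{i + 1:02d}" for i in range(d.n_strains_wild)
    ]
    hosts = ["highbush"] * d.n_strains_highbush + ["wild"] * d.n_strains_wild
    rows = []
    for strain, host in zip(strains, hosts):
        for medium in d.media:
            for matrix in d.matrices:
                rows.append(
                    {
                        "sample_id": f"{strain}_{medium}_{matrix[:3]}",
                        "strain": strain,
                        "host": host,
                        "medium": medium,
                        "matrix": matrix,
                    }
                )
    samples = pd.DataFrame(rows).set_index("sample_id")

    # feature attributes
    width = len(str(d.n_features))
    fids = pd.Index([f"F{i + 1:0{width}d}" for i in range(d.n_features)], name="feature_id")
    features = pd.DataFrame(
        {
            "mz": rng.uniform(*d.mz_range, size=d.n_features),
            "rt_min": rng.uniform(*d.rt_range, size=d.n_features),
            "isotope_flag": rng.random(d.n_features) < d.isotope_fraction,
        },
        index=fids,
    )

    # planted markers: disjoint sets per contrast
    marker_idx = rng.choice(d.n_features, size=total_markers, replace=False)
    truth = {}
    shift = np.zeros((d.n_features, len(samples)))
    group_masks = {
        "medium": (samples["medium"] == d.media[0]).to_numpy(),
        "host": (samples["host"] == "highbush").to_numpy(),
    }
    for ci, contrast in enumerate(CONTRASTS):
        idx = marker_idx[ci * d.n_markers : (ci + 1) * d.n_markers]
        directions = rng.choice([-1.0, 1.0], size=idx.size)
        truth[contrast] = pd.DataFrame(
            {"direction": directions}, index=fids[idx].rename("feature_id")
        )
        delta = d.effect_size * d.log_noise_sd
        shift[np.ix_(idx, np.flatnonzero(group_masks[contrast]))] += np.outer(
            directions * delta, np.ones(int(group_masks[contrast].sum()))
        )

    baseline = rng.normal(d.log_mean, d.log_mean_sd, size=d.n_features)
    noise = rng.normal(0.0, d.log_noise_sd, size=(d.n_features, len(samples)))
    log_area = baseline[:, None] + shift + noise
    areas = np.clip(np.exp(log_area), 0.0, d.area_ceiling)
    areas_df = pd.DataFrame(areas, index=fids, columns=samples.index)

    table = FeatureTable(features=features, areas=areas_df, samples=samples).with_log(
        f"simulated: seed={seed}, {d.n_features} features x {len(samples)} samples, "
        f"{d.n_markers} markers/contrast, effect {d.effect_size} sd"
    )
    return table, GroundTruth(markers=truth)


def simulate_msms(
    peptide: CyclicPeptide,
    mz_noise_sd: float = 0.0,
    dropout: float = 0.0,
    n_contaminants: int = 0,
    seed: int = 0,
) -> MsMsSpectrum:
    """Synthetic MS/MS spectrum of a cyclic peptide.

    Starts from the deduplicated theoretical cyclospectrum, jitters each
    m/z by Gaussian noise, drops each peak independently with
    probability ``dropout`` and adds uniform contaminant peaks between
    the smallest b1 and the precursor. Precursor m/z is exact.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    theo = cyclospectrum(peptide, dedup=True)
    keep = rng.random(theo.size) >= dropout
    mz = theo[keep]
    if mz_noise_sd > 0:
        mz = mz + rng.normal(0.0, mz_noise_sd, size=mz.size)
    intensity = np.full(mz.size, 100.0)
    if n_contaminants > 0:
        cont = rng.uniform(50.0, peptide.precursor_mz, size=n_contaminants)
        mz = np.concatenate([mz, cont])
        intensity = np.concatenate([intensity, np.full(n_contaminants, 20.0)])
    return MsMsSpectrum(
        precursor_mz=peptide.precursor_mz, mz=mz, intensity=intensity, title=repr(peptide)
    )
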