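"""End-to-end workflow orchestration with a single config.

Stages: (simulate) -> filter -> model -> prioritize -> dereplicate ->
annotate/sequence. Every output file carries a header comment with the
tool version, a hash of the configuration and the seed; a manifest of
content hashes makes re-running a completed stage with unchanged inputs
a no-op. Logging goes to standard error with stage-tagged lines; the
machine-readable run report is JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import dereplicate
from .features import (
    FeatureTable,
    filter_features,
    pareto_scale,
    read_feature_table,
    split_by_matrix,
    write_feature_table,
)
from .opls import (
    VIP_SIGNIFICANT,
    classify_model,
    cross_validate_q2,
    fit_oplsda,
    permutation_q2,
    s_plot,
    validate_subset,
    vip_scores,
)
from .peptides import CyclicPeptide, annotate_spectrum
from .sequencing import sequence_candidates
from .simulate import StudyDesign, simulate_study
from .spectra import read_mgf

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; numeric defaults are the protocol's."""

    out_dir: str = "cyclomet_out"
    features_csv: str | None = None
    metadata_csv: str | None = None
    spectra_mgf: str | None = None
    peptide: str | None = None  # e.g. "cyclo(NMePhe-Ala-Ile-Leu-Pro)"
    simulate: bool = False
    contrast: str = "medium"  # metadata column with exactly two levels
    matrix: str = "filtrate"  # which extract matrix to model
    area_min: float = 10_000.0
    mycelium_rt_max: float = 25.0
    log_transform: bool = True
    n_orth: int = 1
    folds: int = 7
    seed: int = 0
    top_n: int = 30
    n_perm: int = 20
    vip_threshold: float = VIP_SIGNIFICANT
    ppm_tol: float = 5.0
    rt_tol: float = 0.5
    msms_tol: float = 0.02
    ring_size: int = 5
    keep: int = 10
    max_mismatches: int = 0
    design: dict = field(default_factory=dict)  # StudyDesign overrides for simulate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _log(stage: str, message: str) -> None:
    print(f"[cyclomet:{stage}] {message}", file=sys.stderr)


def _header(config: PipelineConfig) -> str:
    return f"cyclomet {__version__} | config {config.config_hash} | seed {config.seed}"


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = True) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {_header(config)}\n")
        df.to_csv(fh, index=index)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    """Content-hash bookkeeping for stage resumability."""

    def __init__(self, path: Path):
        self.path = path
        self.state = json.loads(path.read_text()) if path.exists() else {}

    def unchanged(self, stage: str, inputs_hash: str, outputs: list[Path]) -> bool:
        rec = self.state.get(stage)
        return (
            rec is not None
            and rec["inputs"] == inputs_hash
            and all(Path(p).exists() for p in rec["outputs"])
        )

    def record(self, stage: str, inputs_hash: str, outputs: list[Path]) -> None:
        self.state[stage] = {"inputs": inputs_hash, "outputs": [str(p) for p in outputs]}
        self.path.write_text(json.dumps(self.state, indent=2, sort_keys=True))


def _model_contrast(table: FeatureTable, config: PipelineConfig, out: Path) -> dict:
    y = table.samples[config.contrast].to_numpy()
    levels = sorted(pd.unique(y))
    if len(levels) != 2:
        raise PipelineError("model", f"contrast {config.contrast!r} has levels {levels}, need 2")
    X = table.matrix()
    if config.log_transform:
        X = np.log(np.maximum(X, 1.0))
    Xs, constant = pareto_scale(X)
    model = fit_oplsda(Xs, y, n_orth=config.n_orth)
    q2 = cross_validate_q2(Xs, y, n_orth=config.n_orth, folds=config.folds, seed=config.seed)
    vip = vip_scores(model, mz=table.features["mz"], feature_ids=table.features.index)
    splot = s_plot(model, Xs, feature_ids=table.features.index)
    ledger = validate_subset(
        Xs, y, vip, top_n=config.top_n, n_orth=config.n_orth,
        folds=config.folds, seed=config.seed,
        conditions=f"{config.contrast}: {levels[0]} vs {levels[1]} ({config.matrix})",
    )
    perm = permutation_q2(
        Xs, y, n_perm=config.n_perm, n_orth=config.n_orth, folds=config.folds, seed=config.seed
    )
    scores = pd.DataFrame(
        {"t_pred": model.t_pred, "t_orth1": model.t_orth[0] if model.n_orth else 0.0,
         "class": y},
        index=table.samples.index,
    )
    _write_csv(vip, out / "vip.csv", config)
    _write_csv(splot, out / "s_plot.csv", config)
    _write_csv(scores, out / "scores.csv", config)
    ledger.to_csv(out / "validation_ledger.csv", header_comment=_header(config))
    return {
        "levels": [str(v) for v in levels],
        "n_samples": int(table.n_samples),
        "n_features": int(table.n_features),
        "n_constant_features": int(constant.sum()),
        "r2x": model.r2x,
        "r2y": model.r2y,
        "q2": q2,
        "verdict": classify_model(q2),
        "useful_subset": ledger.useful_subset,
        "permutation_q2_median": perm["median"],
        "permutation_q2_p95": perm["p95"],
        "n_vip_significant": int((vip["vip"] > config.vip_threshold).sum()),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": {},
    }

    # --- stage: input (simulate or load) -------------------------------
    if config.simulate:
        stage_in = f"simulate:{config.config_hash}"
        fcsv, mcsv = out / "simulated_features.csv", out / "simulated_metadata.csv"
        if manifest.unchanged("input", stage_in, [fcsv, mcsv]):
            _log("simulate", "unchanged; skipping")
        else:
            design = StudyDesign(**config.design)
            table, truth = simulate_study(design, seed=config.seed)
            write_feature_table(table, fcsv, mcsv, header_comment=_header(config))
            truth_df = pd.concat(
                [df.assign(contrast=c) for c, df in truth.markers.items()]
            )
            _write_csv(truth_df, out / "ground_truth.csv", config)
            manifest.record("input", stage_in, [fcsv, mcsv])
            _log("simulate", f"{table.n_features} features x {table.n_samples} samples")
        features_csv, metadata_csv = fcsv, mcsv
    else:
        if not config.features_csv or not config.metadata_csv:
            raise PipelineError("input", "features_csv and metadata_csv are required")
        features_csv, metadata_csv = Path(config.features_csv), Path(config.metadata_csv)
        for p in (features_csv, metadata_csv):
            if not p.exists():
                raise PipelineError("input", f"missing input file: {p}")
    report["stages"]["input"] = {"features_csv": str(features_csv), "metadata_csv": str(metadata_csv)}

    # --- stage: filter -------------------------------------------------
    try:
        table = read_feature_table(features_csv, metadata_csv)
    except Exception as exc:  # noqa: BLE001 - stage errors carry stage name
        raise PipelineError("filter", str(exc)) from exc
    by_matrix = split_by_matrix(table)
    if config.matrix not in by_matrix:
        raise PipelineError("filter", f"no samples with matrix {config.matrix!r}")
    filtered = filter_features(
        by_matrix[config.matrix], area_min=config.area_min, mycelium_rt_max=config.mycelium_rt_max
    )
    fcsv, mcsv = out / "filtered_features.csv", out / "filtered_metadata.csv"
    write_feature_table(filtered, fcsv, mcsv, header_comment=_header(config))
    _log("filter", filtered.log[-1])
    report["stages"]["filter"] = {
        "matrix": config.matrix,
        "n_features_in": table.n_features,
        "n_features_out": filtered.n_features,
        "n_samples": filtered.n_samples,
        "log": list(filtered.log),
    }

    # --- stage: model + prioritize ------------------------------------
    try:
        model_report = _model_contrast(filtered, config, out)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("model", str(exc)) from exc
    _log("model", f"Q2={model_report['q2']:.3f} ({model_report['verdict']}); "
                  f"useful_subset={model_report['useful_subset']}")
    report["stages"]["model"] = model_report

    vip = pd.read_csv(out / "vip.csv", comment="#", index_col=0)
    top = vip.head(config.top_n)
    _write_csv(top, out / "prioritized_features.csv", config)
    report["stages"]["prioritize"] = {"top_n": config.top_n, "feature_ids": list(top.index[:10])}

    # --- stage: dereplicate prioritized features ----------------------
    rows = []
    for fid in top.index:
        mz = float(filtered.features.loc[fid, "mz"])
        rt = float(filtered.features.loc[fid, "rt_min"])
        for hit in dereplicate(mz, rt, tol_ppm=config.ppm_tol, tol_rt=config.rt_tol):
            rows.append(
                {"feature_id": fid, "mz": mz, "rt_min": rt, "compound": hit.entry.name,
                 "ppm": round(hit.ppm, 2), "delta_rt": round(hit.delta_rt, 3)}
            )
    derep_df = pd.DataFrame(rows, columns=["feature_id", "mz", "rt_min", "compound", "ppm", "delta_rt"])
    _write_csv(derep_df, out / "dereplication.csv", config, index=False)
    _log("derep", f"{len(derep_df)} library hit(s) among top {config.top_n} features")
    report["stages"]["dereplicate"] = {"n_hits": int(len(derep_df))}

    # --- stage: annotate / sequence MS/MS -----------------------------
    if config.spectra_mgf:
        mgf_path = Path(config.spectra_mgf)
        if not mgf_path.exists():
            raise PipelineError("annotate", f"missing input file: {mgf_path}")
        spectra = read_mgf(mgf_path)
        msms_report = []
        records = []
        for i, spec in enumerate(spectra):
            entry: dict = {"spectrum": spec.title or f"spectrum_{i}", "precursor_mz": spec.precursor_mz}
            if config.peptide:
                pep = CyclicPeptide.from_string(config.peptide)
                annotations, coverage = annotate_spectrum(pep, spec, tol=config.msms_tol)
                best = max(coverage, key=coverage.get)
                entry["annotation"] = {"peptide": repr(pep), "best_opening": best,
                                       "coverage": coverage}
                records.extend(
                    {"spectrum": entry["spectrum"], "opening": a.opening, "ion": f"b{a.ordinal}",
                     "theoretical_mz": round(a.theoretical_mz, 4),
                     "observed_mz": None if a.observed_mz is None else round(a.observed_mz, 4),
                     "delta": None if a.delta is None else round(a.delta, 4)}
                    for a in annotations
                )
            cands = sequence_candidates(
                spec.precursor_mz, spec, ring_size=config.ring_size, tol=config.msms_tol,
                keep=config.keep, max_mismatches=config.max_mismatches,
            )
            entry["candidates"] = [
                {"ring": "-".join(c.rotation_key), "matched_peaks": c.matched_peaks,
                 "precursor_delta": round(c.precursor_delta, 4)}
                for c in cands
            ]
            msms_report.append(entry)
        if records:
            _write_csv(pd.DataFrame(records), out / "fragment_annotations.csv", config, index=False)
        (out / "msms.json").write_text(json.dumps({"header": _header(config), "spectra": msms_report}, indent=2))
        _log("msms", f"processed {len(spectra)} spectrum/spectra")
        report["stages"]["msms"] = {"n_spectra": len(spectra)}

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _log("run", f"report written to {out / 'report.json'}")
    return report
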