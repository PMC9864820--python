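"""End-to-end orchestration: simulate → deconvolve → screen → matrix → PCA.

``run_pipeline`` executes the stages in order, collects per-stage counts in
a machine-readable run log, and (optionally) writes every stage artifact to
an output directory. ``recovery_report`` scores pipeline output against the
simulator's planted ground truth — the instrument by which the whole
workflow is validated, since real venom LC-MS surveys carry no ground truth.
All outputs are deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .deconvolution import DeconvolvedToxin, DeconvParams, top_abundant_toxins
from .errors import ConfigurationError, ValidationError, VenomicsError
from .feature_matrix import FeatureMatrix, bin_masses, build_matrix, transform_intensities
from .ordination import OrdinationResult, cluster_separation, run_pca, top_loading_features
from .screening import (
    ConsensusFeature,
    PresenceCall,
    build_database,
    merge_features,
    screen_run,
    write_calls_csv,
    write_features_json,
)
from .simulate import GroundTruth, SimulationConfig, build_clade_panel, synthesize_run
from .spectra_io import Run, read_manifest, read_run, write_run

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RecoveryReport",
    "run_pipeline",
    "recovery_report",
]


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, with study defaults.

    ``n_top`` is the number of abundant toxins extracted per run (default 12,
    the midpoint of the conventional 10–15 band); ``mass_tol`` (1 Da) and
    ``rt_tol`` (0.5 min) define the cross-sample identity rule;
    ``detection_snr`` gates presence calls at 3× the run-local noise floor.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    deconv: DeconvParams = field(default_factory=DeconvParams)
    n_top: int = 12
    mass_tol: float = 1.0
    rt_tol: float = 0.5
    detection_snr: float = 3.0
    noise_floor_abs: float = 1.0
    transform: str = "log10p"
    pca_components: int = 2
    pca_center: bool = True
    pca_scale: bool = False
    seed: int | None = None  # overrides simulation.seed when set
    write_runs: bool = False
    runs_dir: str | None = None  # read runs from here instead of simulating

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=int(self.seed))

    def validate(self) -> None:
        if not 1 <= self.n_top <= 50:
            raise ConfigurationError(f"n_top must lie in [1, 50], got {self.n_top}")
        if self.mass_tol <= 0:
            raise ConfigurationError("mass_tol must be positive")
        if self.rt_tol <= 0:
            raise ConfigurationError("rt_tol must be positive")
        if self.detection_snr <= 0:
            raise ConfigurationError("detection_snr must be positive")
        if self.pca_components < 1:
            raise ConfigurationError("pca_components must be >= 1")
        if self.transform not in ("raw", "log10p", "binary"):
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        self.simulation.validate()

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        doc = dict(doc)
        sim = doc.pop("simulation", {})
        dec = doc.pop("deconv", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        sim_cfg = sim if isinstance(sim, SimulationConfig) else SimulationConfig.from_dict(sim)
        if isinstance(dec, DeconvParams):
            dec_cfg = dec
        else:
            bad = set(dec) - set(DeconvParams.__dataclass_fields__)
            if bad:
                raise ConfigurationError(f"unknown deconv config keys: {sorted(bad)}")
            dec_cfg = DeconvParams(**dec)
        cfg = cls(simulation=sim_cfg, deconv=dec_cfg, **doc)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, Mapping):
            raise ConfigurationError(f"{path}: pipeline config must be a mapping")
        return cls.from_dict(doc)


@dataclass
class RecoveryReport:
    """Ground-truth scoring of pipeline output."""

    recall: float
    feature_fdr: float
    presence_accuracy: float
    mean_abs_mass_error_da: float
    n_expected: int
    n_features: int
    n_matched: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus per-stage counts."""

    config: PipelineConfig
    truth: GroundTruth | None
    runs: dict[str, Run]
    toxins_by_run: dict[str, list[DeconvolvedToxin]]
    features: list[ConsensusFeature]
    calls: list[PresenceCall]
    matrix: FeatureMatrix
    transformed: FeatureMatrix
    ordination: OrdinationResult | None
    separation: dict[str, float]
    recovery: RecoveryReport | None
    counts: dict


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except VenomicsError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis and optionally write all artifacts.

    With ``config.runs_dir`` unset, runs are simulated from the planted clade
    panel; otherwise fixture-JSON/mzML runs and a ``manifest.csv`` are read
    from that directory and no ground truth is available.
    """
    config.validate()

    # ------------------------------------------------------------------ input
    if config.runs_dir is None:
        truth = _stage("simulate", build_clade_panel, config.simulation)
        runs = {
            sid: _stage("simulate", synthesize_run, truth, sid, config.simulation)
            for sid in truth.sample_ids
        }
        manifest = truth.sample_manifest
    else:
        truth = None
        runs_dir = Path(config.runs_dir)
        manifest = read_manifest(runs_dir / "manifest.csv")
        runs = {}
        for meta in manifest:
            candidates = [runs_dir / f"run_{meta.sample_id}.json", runs_dir / f"run_{meta.sample_id}.mzML"]
            path = next((p for p in candidates if p.exists()), None)
            if path is None:
                raise ValidationError(f"[stage read] no run file for sample {meta.sample_id!r}")
            runs[meta.sample_id] = _stage("read", read_run, path, metadata=meta)

    # ------------------------------------------------------------- deconvolve
    toxins_by_run: dict[str, list[DeconvolvedToxin]] = {}
    for sid, run in runs.items():
        try:
            toxins_by_run[sid] = top_abundant_toxins(run, config.n_top, config.deconv)
        except VenomicsError as exc:
            raise type(exc)(f"[stage deconv] sample {sid}: {exc}") from exc

    # ----------------------------------------------------------------- screen
    entries = _stage("screen", build_database, toxins_by_run)
    features = _stage("screen", merge_features, entries, config.mass_tol, config.rt_tol)
    calls: list[PresenceCall] = []
    if features:
        for sid, run in runs.items():
            try:
                calls.extend(
                    screen_run(
                        run,
                        features,
                        detection_snr=config.detection_snr,
                        rt_tol=config.rt_tol,
                        mass_tol=config.mass_tol,
                        eic_mz_tol=config.deconv.eic_mz_tol,
                        noise_floor_abs=config.noise_floor_abs,
                    )
                )
            except VenomicsError as exc:
                raise type(exc)(f"[stage screen] sample {sid}: {exc}") from exc

    # ----------------------------------------------------------------- matrix
    matrix = _stage("matrix", build_matrix, calls, features, manifest)
    transformed = _stage("matrix", transform_intensities, matrix, config.transform)
    bins = bin_masses(matrix) if features else None

    # -------------------------------------------------------------------- pca
    ordination = None
    separation: dict[str, float] = {}
    if matrix.n_samples >= 2 and matrix.n_features >= 1:
        ordination = _stage(
            "pca",
            run_pca,
            transformed,
            n_components=config.pca_components,
            center=config.pca_center,
            scale=config.pca_scale,
        )
        mdf = matrix.manifest
        for level in ("genus", "species"):
            groups = dict(zip(mdf["sample_id"], mdf[level]))
            if len(set(groups.values())) >= 2:
                separation[level] = cluster_separation(ordination, groups)

    # ----------------------------------------------------------------- report
    recovery = None
    if truth is not None and features:
        recovery = recovery_report(
            truth,
            features,
            calls,
            n_top=config.n_top,
            rt_tol=config.rt_tol,
        )

    counts = {
        "samples": len(runs),
        "toxins_per_run": {sid: len(t) for sid, t in toxins_by_run.items()},
        "database_entries": len(entries),
        "features": len(features),
        "present_calls": sum(1 for c in calls if c.present),
        "matrix_nonzero_cells": int((matrix.values.to_numpy() > 0).sum()),
        "mass_bins": bins.counts if bins is not None else {},
    }

    result = PipelineResult(
        config=config,
        truth=truth,
        runs=runs,
        toxins_by_run=toxins_by_run,
        features=features,
        calls=calls,
        matrix=matrix,
        transformed=transformed,
        ordination=ordination,
        separation=separation,
        recovery=recovery,
        counts=counts,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


# ---------------------------------------------------------------------------
# ground-truth scoring


def recovery_report(
    truth: GroundTruth,
    features: Sequence[ConsensusFeature],
    calls: Sequence[PresenceCall],
    n_top: int = 12,
    rt_tol: float = 0.5,
    match_mass_tol: float = 0.5,
) -> RecoveryReport:
    """Score features and presence calls against the planted panel.

    Features are matched one-to-one to planted toxins greedily by ascending
    |Δmass| under |Δmass| ≤ ``match_mass_tol`` and |Δrt| ≤ ``rt_tol``.
    *Recall* is the fraction of discoverable toxins (the union over samples
    of each sample's true ``n_top`` most intense members) that got a matched
    feature; *feature FDR* the fraction of features matching no planted
    toxin; *presence accuracy* the fraction of (matched feature, sample)
    cells whose call agrees with planted membership.
    """
    known_samples = set(truth.sample_ids)
    call_samples = {c.sample_id for c in calls}
    stray = call_samples - known_samples
    if stray:
        raise ValidationError(f"calls reference samples not in ground truth: {sorted(stray)}")

    # discoverable set: per sample, its n_top most intense planted members
    expected: set[str] = set()
    for sid in truth.sample_ids:
        members = truth.members_of(sid)
        members.sort(key=lambda t: -(t.base_intensity * t.member_samples[sid]))
        expected.update(t.toxin_id for t in members[:n_top])

    pairs = []
    for f in features:
        for t in truth.toxins:
            dm = abs(f.consensus_mass - t.neutral_mass)
            dr = abs(f.consensus_rt - t.rt_center)
            if dm <= match_mass_tol and dr <= rt_tol:
                pairs.append((dm, f.feature_id, t.toxin_id))
    pairs.sort()
    matched_f: dict[str, str] = {}
    matched_t: set[str] = set()
    errors = []
    for dm, fid, tid in pairs:
        if fid in matched_f or tid in matched_t:
            continue
        matched_f[fid] = tid
        matched_t.add(tid)
        errors.append(dm)

    n_features = len(features)
    recall = len(matched_t & expected) / len(expected) if expected else 0.0
    fdr = (n_features - len(matched_f)) / n_features if n_features else 0.0

    toxin_by_id = {t.toxin_id: t for t in truth.toxins}
    call_map = {(c.feature_id, c.sample_id): c.present for c in calls}
    n_cells = 0
    n_correct = 0
    for fid, tid in matched_f.items():
        toxin = toxin_by_id[tid]
        for sid in truth.sample_ids:
            predicted = call_map.get((fid, sid), False)
            actual = sid in toxin.member_samples
            n_cells += 1
            n_correct += predicted == actual
    accuracy = n_correct / n_cells if n_cells else 0.0
    mean_err = float(np.mean(errors)) if errors else float("nan")

    return RecoveryReport(
        recall=recall,
        feature_fdr=fdr,
        presence_accuracy=accuracy,
        mean_abs_mass_error_da=mean_err,
        n_expected=len(expected),
        n_features=n_features,
        n_matched=len(matched_f),
    )


# ---------------------------------------------------------------------------
# artifact writing


def _toxins_frame(toxins_by_run: Mapping[str, Sequence[DeconvolvedToxin]]) -> pd.DataFrame:
    rows = []
    for sid, toxins in toxins_by_run.items():
        for t in toxins:
            rows.append(
                {
                    "sample_id": sid,
                    "neutral_mass_da": t.neutral_mass,
                    "rt_apex_min": t.rt_apex,
                    "best_charge": t.best_charge,
                    "charge_states": ";".join(str(z) for z in t.charge_states),
                    "apex_intensity": t.apex_intensity,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "neutral_mass_da",
            "rt_apex_min",
            "best_charge",
            "charge_states",
            "apex_intensity",
        ],
    )


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage artifact plus the machine-readable run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    result.matrix.manifest.to_csv(outdir / "manifest.csv", index=False)
    if result.truth is not None:
        result.truth.to_json(outdir / "ground_truth.json")
    if cfg.write_runs:
        runs_dir = outdir / "runs"
        for sid, run in result.runs.items():
            write_run(run, runs_dir / f"run_{sid}.json", format="fixture_json")

    _toxins_frame(result.toxins_by_run).to_csv(outdir / "toxins.csv", index=False)
    write_features_json(result.features, outdir / "features.json")
    write_calls_csv(result.calls, outdir / "presence_calls.csv")
    result.matrix.to_tsv(outdir / "matrix.tsv")
    result.matrix.to_long_csv(outdir / "matrix_long.csv")
    result.transformed.to_tsv(outdir / "matrix_transformed.tsv")
    if result.features:
        bin_masses(result.matrix).to_csv(outdir / "bin_summary.csv")
    if result.ordination is not None:
        result.ordination.write_csv(outdir)
        report = {
            "explained_variance_ratio": [float(v) for v in result.ordination.explained_variance_ratio],
            "separation": result.separation,
            "top_loadings": {
                col: top_loading_features(result.ordination, j + 1, k=5).to_dict("records")
                for j, col in enumerate(result.ordination.scores.columns)
            },
        }
        with open(outdir / "pca_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1)
            fh.write("\n")
    if result.recovery is not None:
        with open(outdir / "recovery.json", "w", encoding="utf-8") as fh:
            json.dump(result.recovery.to_dict(), fh, indent=1)
            fh.write("\n")

    try:
        pkg_version = _pkg_version("venomics")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    log = {
        "package_version": pkg_version,
        "parameters": cfg.to_dict(),
        "counts": result.counts,
    }
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, default=str)
        fh.write("\n")
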