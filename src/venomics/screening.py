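"""Cross-sample mass screening: the pooled toxin database and presence calls.

The abundant toxins extracted from every run are pooled into a database,
database entries are merged into consensus features under the identity rule
"same toxin ⇔ all masses within 1 Da of each other AND same retention time
(|ΔRT| ≤ rt_tol)", and every run is then re-screened for every feature at
its recorded charge states to call presence or absence with an EIC apex
against a run-local noise floor.

The "within 1 Da of each other" wording is read as a clique condition —
complete-linkage agglomerative clustering — not single-linkage chaining:
a pair 1.4 Da apart never ends up in one feature even if a third entry sits
between them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .deconvolution import DeconvolvedToxin, extract_eic
from .errors import ValidationError
from .simulate import PROTON_MASS
from .spectra_io import Run

__all__ = [
    "ToxinEntry",
    "ConsensusFeature",
    "PresenceCall",
    "build_database",
    "merge_features",
    "screen_run",
    "write_features_json",
    "read_features_json",
    "write_calls_csv",
]


@dataclass
class ToxinEntry:
    """One database entry: an abundant toxin with its source-run provenance."""

    entry_id: str
    neutral_mass: float
    rt_apex: float
    charge_states: tuple[int, ...]
    source_sample: str
    apex_intensity: float
    best_charge: int


@dataclass
class ConsensusFeature:
    """A cross-sample toxin feature: intensity-weighted consensus mass and RT."""

    feature_id: str
    consensus_mass: float
    consensus_rt: float
    member_entries: list[ToxinEntry]

    def check_clique(self, mass_tol: float, rt_tol: float) -> None:
        masses = [e.neutral_mass for e in self.member_entries]
        rts = [e.rt_apex for e in self.member_entries]
        if max(masses) - min(masses) > mass_tol + 1e-12:
            raise ValidationError(f"{self.feature_id}: member mass span exceeds {mass_tol} Da")
        if max(rts) - min(rts) > rt_tol + 1e-12:
            raise ValidationError(f"{self.feature_id}: member rt span exceeds {rt_tol} min")


@dataclass
class PresenceCall:
    feature_id: str
    sample_id: str
    present: bool
    intensity: float
    matched_mass: float | None = None


# ---------------------------------------------------------------------------


def build_database(
    toxins_by_run: Mapping[str, Sequence[DeconvolvedToxin]] | Sequence[Sequence[DeconvolvedToxin]],
) -> list[ToxinEntry]:
    """Concatenate per-run abundant toxins into database entries (no merging)."""
    if isinstance(toxins_by_run, Mapping):
        groups = list(toxins_by_run.items())
    else:
        groups = [(lst[0].sample_id if lst else f"run{i}", lst) for i, lst in enumerate(toxins_by_run)]
    seen: set[str] = set()
    entries: list[ToxinEntry] = []
    for sample_id, toxins in groups:
        if sample_id in seen:
            raise ValidationError(f"duplicate sample id in database input: {sample_id!r}")
        seen.add(sample_id)
        for i, t in enumerate(toxins):
            if t.sample_id != sample_id:
                raise ValidationError(
                    f"toxin record for {t.sample_id!r} listed under sample {sample_id!r}"
                )
            entries.append(
                ToxinEntry(
                    entry_id=f"{sample_id}:{i + 1:02d}",
                    neutral_mass=t.neutral_mass,
                    rt_apex=t.rt_apex,
                    charge_states=tuple(t.charge_states),
                    source_sample=sample_id,
                    apex_intensity=t.apex_intensity,
                    best_charge=t.best_charge,
                )
            )
    return entries


def _scaled_distance(a: ToxinEntry, b: ToxinEntry, mass_tol: float, rt_tol: float) -> float:
    return max(abs(a.neutral_mass - b.neutral_mass) / mass_tol, abs(a.rt_apex - b.rt_apex) / rt_tol)


def merge_features(
    entries: Sequence[ToxinEntry],
    mass_tol: float = 1.0,
    rt_tol: float = 0.5,
) -> list[ConsensusFeature]:
    """Complete-linkage merge of database entries into consensus features.

    Two clusters merge only while EVERY cross pair satisfies both
    ``|Δmass| ≤ mass_tol`` and ``|Δrt| ≤ rt_tol``; merges proceed in order
    of ascending complete-linkage distance (the larger of the two tolerance-
    scaled gaps), with ties broken toward the cluster pair containing the
    lower minimum mass (then earlier rt). Consensus mass and rt are
    intensity-weighted means of the members.
    """
    if mass_tol <= 0 or rt_tol <= 0:
        raise ValidationError("mass_tol and rt_tol must be positive")
    clusters: list[list[ToxinEntry]] = [[e] for e in entries]
    n = len(clusters)
    masses = np.array([e.neutral_mass for e in entries])
    rts = np.array([e.rt_apex for e in entries])
    # scaled Chebyshev distance; complete linkage updates by pairwise max
    dist = np.maximum(
        np.abs(masses[:, None] - masses[None, :]) / mass_tol,
        np.abs(rts[:, None] - rts[None, :]) / rt_tol,
    )
    min_mass = masses.copy()
    min_rt = rts.copy()
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                d = dist[i, j]
                if d > 1.0:
                    continue
                key = (d, min(min_mass[i], min_mass[j]), min(min_rt[i], min_rt[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        dist[i, :] = np.maximum(dist[i, :], dist[j, :])
        dist[:, i] = dist[i, :]
        min_mass[i] = min(min_mass[i], min_mass[j])
        min_rt[i] = min(min_rt[i], min_rt[j])
        active.remove(j)
    clusters = [clusters[i] for i in active]

    features: list[ConsensusFeature] = []
    for members in clusters:
        weights = np.array([max(e.apex_intensity, 0.0) for e in members])
        masses = np.array([e.neutral_mass for e in members])
        rts = np.array([e.rt_apex for e in members])
        if weights.sum() > 0:
            cmass = float(np.average(masses, weights=weights))
            crt = float(np.average(rts, weights=weights))
        else:
            cmass = float(masses.mean())
            crt = float(rts.mean())
        features.append(
            ConsensusFeature(
                feature_id="",
                consensus_mass=cmass,
                consensus_rt=crt,
                member_entries=sorted(members, key=lambda e: e.entry_id),
            )
        )
    features.sort(key=lambda f: (f.consensus_mass, f.consensus_rt))
    for k, f in enumerate(features):
        f.feature_id = f"F{k + 1:03d}"
        f.check_clique(mass_tol, rt_tol)
    return features


# ---------------------------------------------------------------------------


def screen_run(
    run: Run,
    features: Sequence[ConsensusFeature],
    detection_snr: float = 3.0,
    rt_tol: float = 0.5,
    mass_tol: float = 1.0,
    eic_mz_tol: float = 0.05,
    noise_floor_abs: float = 1.0,
) -> list[PresenceCall]:
    """Call presence/absence of every consensus feature in one run.

    For each charge state recorded among a feature's members, an EIC is
    extracted at the implied m/z. The feature is present iff the best EIC
    apex within ``rt_tol`` of the consensus rt reaches
    ``detection_snr ×`` the run-local noise floor (median non-zero EIC value
    outside the rt window; ``noise_floor_abs`` when the off-window trace is
    silent) AND the centroid at the apex re-deconvolves to within
    ``mass_tol`` of the consensus mass. Absent calls carry intensity 0.
    """
    if not features:
        raise ValidationError("features must be non-empty")
    rt = run.rt
    calls: list[PresenceCall] = []
    for feat in features:
        charges = sorted({z for e in feat.member_entries for z in e.charge_states})
        best_intensity = 0.0
        best_mass: float | None = None
        for z in charges:
            target_mz = (feat.consensus_mass + z * PROTON_MASS) / z
            if not (run.mz_min <= target_mz <= run.mz_max):
                continue
            eic = extract_eic(run, target_mz, eic_mz_tol)
            in_rt = np.abs(rt - feat.consensus_rt) <= rt_tol
            if not np.any(in_rt):
                continue
            outside = eic.intensity[~in_rt]
            nz = outside[outside > 0]
            floor = float(np.median(nz)) if nz.size else noise_floor_abs
            masked = np.where(in_rt, eic.intensity, -np.inf)
            apex_idx = int(np.argmax(masked))
            apex = float(eic.intensity[apex_idx])
            if apex < detection_snr * floor or apex <= 0:
                continue
            spectrum = run.spectra[apex_idx]
            a = np.searchsorted(spectrum.mz, target_mz - eic_mz_tol, side="left")
            b = np.searchsorted(spectrum.mz, target_mz + eic_mz_tol, side="right")
            if b <= a:
                continue
            seg = slice(a, b)
            local = int(np.argmax(spectrum.intensity[seg]))
            mass_obs = z * (float(spectrum.mz[seg][local]) - PROTON_MASS)
            if abs(mass_obs - feat.consensus_mass) > mass_tol:
                continue
            if apex > best_intensity:
                best_intensity = apex
                best_mass = mass_obs
        calls.append(
            PresenceCall(
                feature_id=feat.feature_id,
                sample_id=run.metadata.sample_id,
                present=best_mass is not None,
                intensity=best_intensity if best_mass is not None else 0.0,
                matched_mass=best_mass,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# artifact I/O


def write_features_json(features: Sequence[ConsensusFeature], path: str | Path) -> None:
    doc = [asdict(f) for f in features]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_features_json(path: str | Path) -> list[ConsensusFeature]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    features = []
    for f in doc:
        members = [
            ToxinEntry(
                entry_id=e["entry_id"],
                neutral_mass=e["neutral_mass"],
                rt_apex=e["rt_apex"],
                charge_states=tuple(e["charge_states"]),
                source_sample=e["source_sample"],
                apex_intensity=e["apex_intensity"],
                best_charge=e["best_charge"],
            )
            for e in f["member_entries"]
        ]
        features.append(
            ConsensusFeature(
                feature_id=f["feature_id"],
                consensus_mass=f["consensus_mass"],
                consensus_rt=f["consensus_rt"],
                member_entries=members,
            )
        )
    return features


def write_calls_csv(calls: Iterable[PresenceCall], path: str | Path) -> None:
    rows = [
        {
            "feature_id": c.feature_id,
            "sample_id": c.sample_id,
            "present": c.present,
            "intensity": c.intensity,
            "matched_mass_da": "" if c.matched_mass is None else c.matched_mass,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["feature_id", "sample_id", "present", "intensity", "matched_mass_da"]
    ).to_csv(path, index=False)


def read_calls_csv(path: str | Path) -> list[PresenceCall]:
    df = pd.read_csv(path)
    calls = []
    for _, row in df.iterrows():
        matched = row["matched_mass_da"]
        calls.append(
            PresenceCall(
                feature_id=str(row["feature_id"]),
                sample_id=str(row["sample_id"]),
                present=bool(row["present"]),
                intensity=float(row["intensity"]),
                matched_mass=None if pd.isna(matched) else float(matched),
            )
        )
    return calls
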