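"""Samples × features intensity matrices, mass-bin summaries, heatmap export.

The matrix realizes the heatmap semantics of a cross-sample venom survey:
rows are consensus (mass, rt) features ordered by ascending mass, columns
are samples ordered genus → species → locality, cells hold EIC apex
intensities with 0 meaning absent. Mass bins follow the field's taxonomy —
<5 kDa peptides, 5–9 kDa (three-finger toxins, Kunitz-type inhibitors),
13–15 kDa (phospholipase A2), >15 kDa — plus an explicit 9–13 kDa
"unclassified" bin for the range that taxonomy leaves unaddressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .screening import ConsensusFeature, PresenceCall
from .spectra_io import SampleMetadata

__all__ = [
    "FeatureMatrix",
    "MassBinSummary",
    "MASS_BIN_LABELS",
    "build_matrix",
    "bin_masses",
    "transform_intensities",
]

MASS_BIN_LABELS = ("<5 kDa", "5-9 kDa", "9-13 kDa", "13-15 kDa", ">15 kDa")


def mass_bin(mass: float) -> str:
    """Bin a neutral mass: [0,5000), [5000,9000], (9000,13000), [13000,15000], (15000,inf)."""
    if mass <= 0:
        raise ValidationError(f"mass must be positive, got {mass}")
    if mass < 5000.0:
        return MASS_BIN_LABELS[0]
    if mass <= 9000.0:
        return MASS_BIN_LABELS[1]
    if mass < 13000.0:
        return MASS_BIN_LABELS[2]
    if mass <= 15000.0:
        return MASS_BIN_LABELS[3]
    return MASS_BIN_LABELS[4]


@dataclass
class MassBinSummary:
    """Feature counts per mass bin; counts always sum to the feature total."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(self.counts[label] for label in MASS_BIN_LABELS)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"bin": list(MASS_BIN_LABELS), "count": [self.counts[b] for b in MASS_BIN_LABELS]}
        ).to_csv(path, index=False)


@dataclass
class FeatureMatrix:
    """An intensity matrix (features × samples) with its feature and sample tables.

    ``values`` is indexed by feature_id (rows, ascending consensus mass) with
    sample-id columns ordered genus → species → locality → sample id.
    ``transform`` records which intensity transform has been applied.
    """

    values: pd.DataFrame
    features: pd.DataFrame  # feature_id, consensus_mass_da, consensus_rt_min
    manifest: pd.DataFrame  # sample_id, genus, species, locality, sex
    transform: str = "raw"

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.features["feature_id"]):
            raise ValidationError("values rows must align with the feature table")
        if list(self.values.columns) != list(self.manifest["sample_id"]):
            raise ValidationError("values columns must align with the manifest")
        if (self.values.values < 0).any():
            raise ValidationError("matrix intensities must be non-negative")
        masses = self.features["consensus_mass_da"].to_numpy()
        rts = self.features["consensus_rt_min"].to_numpy()
        order = np.lexsort((rts, masses))
        if not np.array_equal(order, np.arange(len(masses))):
            raise ValidationError("features must be ordered by ascending mass (ties by rt)")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Heatmap-ready export: mass/rt columns followed by ordered sample columns."""
        out = self.features.set_index("feature_id").join(self.values)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    def to_long_csv(self, path: str | Path) -> None:
        long = self.values.stack().rename("intensity").reset_index()
        long.columns = ["feature_id", "sample_id", "intensity"]
        long.to_csv(path, index=False)


def _manifest_frame(manifest: Sequence[SampleMetadata]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "genus": s.genus,
                "species": s.species,
                "locality": s.locality,
                "sex": s.sex,
            }
            for s in manifest
        ]
    )
    return df.sort_values(
        ["genus", "species", "locality", "sample_id"], kind="stable"
    ).reset_index(drop=True)


def build_matrix(
    calls: Iterable[PresenceCall],
    features: Sequence[ConsensusFeature],
    manifest: Sequence[SampleMetadata],
) -> FeatureMatrix:
    """Assemble presence calls into the ordered intensity matrix.

    Cells take the call intensity (0 when absent); (feature, sample) pairs
    with no call at all are 0. Calls referencing unknown features or samples
    raise a validation error.
    """
    mdf = _manifest_frame(manifest)
    feat_df = pd.DataFrame(
        [
            {
                "feature_id": f.feature_id,
                "consensus_mass_da": f.consensus_mass,
                "consensus_rt_min": f.consensus_rt,
            }
            for f in features
        ]
    ).sort_values(["consensus_mass_da", "consensus_rt_min"], kind="stable").reset_index(drop=True)

    known_features = set(feat_df["feature_id"])
    known_samples = set(mdf["sample_id"])
    values = pd.DataFrame(
        0.0, index=list(feat_df["feature_id"]), columns=list(mdf["sample_id"])
    )
    for call in calls:
        if call.feature_id not in known_features:
            raise ValidationError(f"presence call references unknown feature {call.feature_id!r}")
        if call.sample_id not in known_samples:
            raise ValidationError(f"presence call references unknown sample {call.sample_id!r}")
        values.loc[call.feature_id, call.sample_id] = call.intensity if call.present else 0.0
    return FeatureMatrix(values=values, features=feat_df, manifest=mdf)


def bin_masses(features: Sequence[ConsensusFeature] | Sequence[float] | FeatureMatrix) -> MassBinSummary:
    """Count features per mass bin; accepts features, raw masses, or a matrix."""
    if isinstance(features, FeatureMatrix):
        masses = list(features.features["consensus_mass_da"])
    else:
        masses = [
            f.consensus_mass if isinstance(f, ConsensusFeature) else float(f) for f in features
        ]
    if not masses:
        raise ValidationError("bin_masses requires at least one feature")
    counts = {label: 0 for label in MASS_BIN_LABELS}
    for m in masses:
        counts[mass_bin(m)] += 1
    return MassBinSummary(counts=counts)


def transform_intensities(matrix: FeatureMatrix, mode: str = "log10p") -> FeatureMatrix:
    """Return a transformed copy of the matrix; zeros stay zero in every mode.

    ``log10p`` maps v → log10(1 + v/floor) with floor = the smallest nonzero
    value of the matrix, compressing the ~100-fold intensity spreads typical
    of venom toxins while preserving the zero (absence) pattern. ``binary``
    maps any positive value to 1. ``raw`` is the identity.
    """
    vals = matrix.values
    if mode == "raw":
        out = vals.copy()
    elif mode == "binary":
        out = (vals > 0).astype(float)
    elif mode == "log10p":
        arr = vals.to_numpy()
        nonzero = arr[arr > 0]
        if nonzero.size == 0:
            out = vals.copy()
        else:
            floor = float(nonzero.min())
            out = pd.DataFrame(
                np.log10(1.0 + arr / floor), index=vals.index, columns=vals.columns
            )
    else:
        raise ConfigurationError(f"unknown intensity transform: {mode!r}")
    return FeatureMatrix(
        values=out,
        features=matrix.features.copy(),
        manifest=matrix.manifest.copy(),
        transform=mode,
    )
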