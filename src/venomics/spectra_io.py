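"""Reading, writing and in-memory modelling of centroided LC-MS runs.

A :class:`Run` is a time-ordered list of centroid spectra from one venom
acquisition plus its sample metadata. Two on-disk formats are supported:

* **mzML** (plain, centroid-only) — parsed with a small stdlib XML reader
  (cvParam accessions; 32/64-bit float arrays, zlib or uncompressed) and
  written by a minimal emitter (64-bit float arrays, no compression).
* **fixture JSON** — a lossless plain-text format used by the simulator and
  the test suite: ``{"sample": {...}, "mz_min", "mz_max", "spectra":
  [{"rt_minutes", "mz", "intensity"}, ...]}``.

Retention time is expressed in **minutes** everywhere; mzML scan times
recorded in seconds are converted on read.
"""

from __future__ import annotations

import base64
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import quoteattr

import numpy as np
import pandas as pd

from .errors import ParseError, UnsupportedModeError, ValidationError

__all__ = [
    "SampleMetadata",
    "Spectrum",
    "Run",
    "Chromatogram",
    "read_run",
    "write_run",
    "total_ion_chromatogram",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ["sample_id", "genus", "species", "locality", "sex"]


@dataclass(frozen=True)
class SampleMetadata:
    """Provenance of one venom sample (unknown fields default to ``"unknown"``)."""

    sample_id: str
    genus: str = "unknown"
    species: str = "unknown"
    locality: str = "unknown"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")


@dataclass
class Spectrum:
    """One centroid spectrum: strictly increasing m/z with non-negative intensities.

    Centroids are sorted on construction; exact duplicate m/z values are
    merged by summing their intensities so the strict-ordering invariant
    always holds.
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise ValidationError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and (not np.all(np.isfinite(mz)) or not np.all(np.isfinite(inten))):
            raise ValidationError("non-finite m/z or intensity value in spectrum")
        if np.any(inten < 0):
            raise ValidationError("negative intensity in spectrum")
        if mz.size:
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            if np.any(np.diff(mz) == 0.0):
                uniq, inverse = np.unique(mz, return_inverse=True)
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, inten)
                mz, inten = uniq, summed
        self.mz = mz
        self.intensity = inten

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """A complete LC-MS acquisition: metadata plus rt-ordered spectra."""

    metadata: SampleMetadata
    spectra: list[Spectrum] = field(default_factory=list)
    mz_min: float = 500.0
    mz_max: float = 5500.0

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValidationError("mz_min must be < mz_max")
        self.spectra = sorted(self.spectra, key=lambda s: s.rt)
        rts = np.array([s.rt for s in self.spectra])
        if rts.size > 1 and np.any(np.diff(rts) <= 0):
            raise ValidationError("spectra retention times must be strictly increasing")
        eps = 1e-9
        for i, s in enumerate(self.spectra):
            if len(s) and (s.mz[0] < self.mz_min - eps or s.mz[-1] > self.mz_max + eps):
                raise ValidationError(
                    f"spectrum {i} contains centroids outside the acquisition "
                    f"window [{self.mz_min}, {self.mz_max}]"
                )

    @property
    def rt(self) -> np.ndarray:
        return np.array([s.rt for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class Chromatogram:
    """A (rt, intensity) trace — the result of TIC or EIC extraction."""

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.rt.shape != self.intensity.shape:
            raise ValidationError("chromatogram rt/intensity shape mismatch")

    def __len__(self) -> int:
        return int(self.rt.size)


def total_ion_chromatogram(run: Run) -> Chromatogram:
    """Sum each spectrum's centroid intensities: one TIC point per spectrum."""
    rt = run.rt
    tic = np.array([float(s.intensity.sum()) if len(s) else 0.0 for s in run.spectra])
    return Chromatogram(rt, tic)


# ---------------------------------------------------------------------------
# format detection


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("mzml", "fixture_json"):
            raise ValidationError(f"unknown run format: {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix == ".json":
        return "fixture_json"
    raise ValidationError(f"cannot infer run format from path {path!s}")


# ---------------------------------------------------------------------------
# fixture JSON


def _run_to_fixture_dict(run: Run) -> dict:
    return {
        "format": "venomics-run",
        "sample": {
            "sample_id": run.metadata.sample_id,
            "genus": run.metadata.genus,
            "species": run.metadata.species,
            "locality": run.metadata.locality,
            "sex": run.metadata.sex,
        },
        "mz_min": run.mz_min,
        "mz_max": run.mz_max,
        "spectra": [
            {"rt_minutes": s.rt, "mz": s.mz.tolist(), "intensity": s.intensity.tolist()}
            for s in run.spectra
        ],
    }


def _fixture_dict_to_run(doc: dict, path: str | Path) -> Run:
    try:
        sample = doc["sample"]
        meta = SampleMetadata(
            sample_id=sample["sample_id"],
            genus=sample.get("genus", "unknown"),
            species=sample.get("species", "unknown"),
            locality=sample.get("locality", "unknown"),
            sex=sample.get("sex", "unknown"),
        )
        spectra = []
        for i, entry in enumerate(doc["spectra"]):
            try:
                spectra.append(
                    Spectrum(
                        rt=float(entry["rt_minutes"]),
                        mz=np.asarray(entry["mz"], dtype=np.float64),
                        intensity=np.asarray(entry["intensity"], dtype=np.float64),
                    )
                )
            except (KeyError, TypeError, ValueError, ValidationError) as exc:
                raise ParseError(f"{path}: malformed spectrum {i}: {exc}") from exc
        return Run(
            metadata=meta,
            spectra=spectra,
            mz_min=float(doc["mz_min"]),
            mz_max=float(doc["mz_max"]),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed fixture run: {exc}") from exc


# ---------------------------------------------------------------------------
# mzML

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id={run_id}>
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def _mzml_spectrum_xml(index: int, spectrum: Spectrum, mz_min: float, mz_max: float) -> str:
    mz_b64 = _b64(spectrum.mz)
    int_b64 = _b64(spectrum.intensity)
    return f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(spectrum)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{spectrum.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
            <scanWindowList count="1">
              <scanWindow>
                <cvParam cvRef="MS" accession="MS:1000501" name="scan window lower limit" value="{mz_min!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
                <cvParam cvRef="MS" accession="MS:1000500" name="scan window upper limit" value="{mz_max!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              </scanWindow>
            </scanWindowList>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def _write_mzml(run: Run, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(run_id=quoteattr(run.metadata.sample_id), count=len(run)))
        for i, s in enumerate(run.spectra):
            fh.write(_mzml_spectrum_xml(i, s, run.mz_min, run.mz_max))
        fh.write(_MZML_FOOTER)


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(array_elem) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib or plain)."""
    import zlib

    dtype = "<f8"
    compressed = False
    binary_text = ""
    for child in array_elem:
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":  # 32-bit float
                dtype = "<f4"
            elif acc == "MS:1000574":  # zlib compression
                compressed = True
        elif name == "binary":
            binary_text = child.text or ""
    raw = base64.b64decode(binary_text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_mzml_spectrum(elem, index: int, path: Path) -> tuple[Spectrum, float | None, float | None]:
    accessions = {
        c.get("accession"): c for c in elem.iter() if _localname(c.tag) == "cvParam"
    }
    if "MS:1000128" in accessions:  # profile spectrum
        raise UnsupportedModeError(
            f"{path}: spectrum {index} is profile mode; this pipeline requires "
            "centroided data"
        )
    rt_param = accessions.get("MS:1000016")
    if rt_param is None:
        raise ParseError(f"{path}: malformed spectrum {index}: no scan start time")
    rt = float(rt_param.get("value"))
    if rt_param.get("unitName", "minute") in ("second", "s"):
        rt /= 60.0
    lo_param = accessions.get("MS:1000501")
    hi_param = accessions.get("MS:1000500")
    mz_lo = float(lo_param.get("value")) if lo_param is not None else None
    mz_hi = float(hi_param.get("value")) if hi_param is not None else None

    mz = np.empty(0)
    inten = np.empty(0)
    for arr in elem.iter():
        if _localname(arr.tag) != "binaryDataArray":
            continue
        kinds = {c.get("accession") for c in arr if _localname(c.tag) == "cvParam"}
        values = _decode_binary_array(arr)
        if "MS:1000514" in kinds:
            mz = values
        elif "MS:1000515" in kinds:
            inten = values
    return Spectrum(rt=rt, mz=mz, intensity=inten), mz_lo, mz_hi


def _read_mzml(path: Path, metadata: SampleMetadata | None) -> Run:
    import xml.etree.ElementTree as ET

    spectra: list[Spectrum] = []
    mz_lo: float | None = None
    mz_hi: float | None = None
    index = 0
    try:
        for _event, elem in ET.iterparse(str(path), events=("end",)):
            if _localname(elem.tag) != "spectrum":
                continue
            try:
                spectrum, lo, hi = _parse_mzml_spectrum(elem, index, path)
            except (UnsupportedModeError, ParseError):
                raise
            except (TypeError, ValueError, ValidationError) as exc:
                raise ParseError(f"{path}: malformed spectrum {index}: {exc}") from exc
            spectra.append(spectrum)
            mz_lo = lo if lo is not None else mz_lo
            mz_hi = hi if hi is not None else mz_hi
            elem.clear()
            index += 1
    except ET.ParseError as exc:
        raise ParseError(f"{path}: malformed mzML (after spectrum {index}): {exc}") from exc
    if metadata is None:
        metadata = SampleMetadata(sample_id=Path(path).stem)
    if mz_lo is None or mz_hi is None:
        # no scan window recorded: fall back to the observed centroid range
        all_mz = np.concatenate([s.mz for s in spectra if len(s)]) if spectra else np.array([])
        mz_lo = float(np.floor(all_mz.min())) if all_mz.size else 0.0
        mz_hi = float(np.ceil(all_mz.max())) if all_mz.size else 1.0
        if not mz_lo < mz_hi:
            mz_lo, mz_hi = mz_lo - 0.5, mz_lo + 0.5
    return Run(metadata=metadata, spectra=spectra, mz_min=mz_lo, mz_max=mz_hi)


# ---------------------------------------------------------------------------
# public I/O


def read_run(
    path: str | Path,
    format: str | None = None,
    metadata: SampleMetadata | None = None,
) -> Run:
    """Read one LC-MS run from disk.

    Parameters
    ----------
    path
        File to read; the format is inferred from the suffix (``.mzml`` /
        ``.json``) when not given explicitly.
    format
        ``"mzml"`` or ``"fixture_json"``.
    metadata
        Optional sample metadata to attach; mzML files carry only the run id,
        so genus/species/locality come from a manifest when available.

    Raises
    ------
    ParseError
        If the file is malformed (the message names the offending spectrum).
    UnsupportedModeError
        If the mzML data are profile-mode rather than centroided.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "mzml":
        return _read_mzml(path, metadata)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: cannot parse fixture JSON: {exc}") from exc
    run = _fixture_dict_to_run(doc, path)
    if metadata is not None:
        run.metadata = metadata
    return run


def write_run(run: Run, path: str | Path, format: str | None = None) -> None:
    """Write a run to disk; lossless for fixture JSON, full precision for mzML."""
    for i, s in enumerate(run.spectra):
        if len(s) and (not np.all(np.isfinite(s.mz)) or not np.all(np.isfinite(s.intensity))):
            raise ValidationError(f"spectrum {i} contains non-finite values")
    fmt = _infer_format(path, format)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mzml":
        _write_mzml(run, path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_run_to_fixture_dict(run), fh)
            fh.write("\n")


# ---------------------------------------------------------------------------
# sample manifest


def write_manifest(samples: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "genus": s.genus,
            "species": s.species,
            "locality": s.locality,
            "sex": s.sex,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    samples = [SampleMetadata(**{c: row[c] for c in MANIFEST_COLUMNS}) for _, row in df.iterrows()]
    ids = [s.sample_id for s in samples]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{path}: duplicate sample ids in manifest")
    return samples
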