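"""Spectrum container and serum-spectrum I/O.

A MALDI-TOF acquisition is stored as a pair of equal-length arrays:
an ascending m/z grid (Da) and nonnegative intensities (arbitrary
units before normalization, percent of the base peak after).  Each
acquisition carries the sample it was spotted from, its replicate
number on the target plate, and whether it is a serum sample or a
matrix blank.

The canonical on-disk format is two-column delimited text (CSV or TSV,
autodetected) with ``#``-prefixed header lines for metadata.  A minimal
mzML profile is supported for interchange: writing emits a bare
spectrum list with 64-bit uncompressed arrays; reading handles 32/64-bit
float arrays, plain or zlib-compressed.
"""

from __future__ import annotations

import base64
import warnings
import xml.sax.saxutils
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "CohortManifest",
    "SpectrumValidationError",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
]


class SpectrumValidationError(ValueError):
    """Raised when arrays violate the spectrum invariants."""


class SpectrumParseError(ValueError):
    """Raised when a file cannot be parsed as a spectrum."""


@dataclass
class Spectrum:
    """One acquisition: intensities on an ascending m/z grid.

    Parameters
    ----------
    mz
        Strictly increasing m/z values in Da.
    intensity
        Nonnegative intensities, same length as `mz`.
    sample_id
        Identifier of the serum sample (or blank) the spot came from.
    replicate_id
        1-based spot replicate number on the target plate.
    role
        ``"sample"`` or ``"matrix_blank"``.
    processing_log
        Ordered descriptors of the preprocessing steps already applied.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: int = 1
    role: str = "sample"
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumValidationError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise SpectrumValidationError(
                f"length mismatch: {len(self.mz)} m/z vs {len(self.intensity)} intensities"
            )
        if len(self.mz) < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if np.any(~np.isfinite(self.mz)) or np.any(~np.isfinite(self.intensity)):
            raise SpectrumValidationError("nonfinite values in spectrum arrays")
        if np.any(np.diff(self.mz) <= 0):
            raise SpectrumValidationError("m/z values must be strictly increasing")
        # NB: small negative intensities are tolerated in memory (smoothing
        # overshoot); they are clipped by baseline subtraction, and files
        # with negative intensities are rejected on read.
        if self.role not in ("sample", "matrix_blank"):
            raise SpectrumValidationError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.mz)

    def copy_with(self, intensity: np.ndarray | None = None,
                  mz: np.ndarray | None = None, log_entry: str | None = None) -> "Spectrum":
        """Return a copy, optionally replacing arrays and appending to the log."""
        log = list(self.processing_log)
        if log_entry is not None:
            log.append(log_entry)
        return Spectrum(
            mz=self.mz.copy() if mz is None else np.asarray(mz, float),
            intensity=self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            role=self.role,
            processing_log=log,
        )


@dataclass
class CohortManifest:
    """Index of a cohort on disk: samples, labels, replicate files, blanks."""

    samples: dict[str, dict]          # sample_id -> {"label": str, "files": [paths]}
    blank_files: list[str]
    label_set: list[str]

    def validate(self, root: Path | str = ".") -> None:
        root = Path(root)
        for sid, rec in self.samples.items():
            if rec["label"] not in self.label_set:
                raise SpectrumValidationError(
                    f"sample {sid}: label {rec['label']!r} not in declared set {self.label_set}"
                )
            for f in rec["files"]:
                if not (root / f).exists():
                    raise SpectrumParseError(f"sample {sid}: missing file {f}")
        for f in self.blank_files:
            if not (root / f).exists():
                raise SpectrumParseError(f"missing blank file {f}")


# ---------------------------------------------------------------------------
# delimited text

def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def _read_delimited(path: Path) -> Spectrum:
    meta = {"sample_id": "", "replicate_id": 1, "role": "sample"}
    log: list[str] = []
    mz_list: list[float] = []
    int_list: list[float] = []
    delim: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    val = val.strip()
                    if key == "replicate_id":
                        meta["replicate_id"] = int(val)
                    elif key in ("sample_id", "role"):
                        meta[key] = val
                    elif key == "log":
                        log.append(val)
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            parts = line.split(delim)
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                m, i = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: nonnumeric value ({exc})") from None
            if i < 0:
                raise SpectrumValidationError(f"{path}:{lineno}: negative intensity {i}")
            mz_list.append(m)
            int_list.append(i)
    if len(mz_list) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    mz = np.array(mz_list)
    inten = np.array(int_list)
    order = np.argsort(mz, kind="stable")
    if np.any(order != np.arange(len(mz))):
        warnings.warn(f"{path}: m/z not ascending; re-sorted", stacklevel=3)
        mz, inten = mz[order], inten[order]
    # duplicate m/z rows arise from export rounding: average them (idempotent)
    uniq, inverse, counts = np.unique(mz, return_inverse=True, return_counts=True)
    if len(uniq) != len(mz):
        warnings.warn(f"{path}: duplicated m/z values averaged", stacklevel=3)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, inten)
        mz, inten = uniq, summed / counts
    return Spectrum(mz=mz, intensity=inten, processing_log=log, **meta)


def _write_delimited(spec: Spectrum, path: Path, delim: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {spec.sample_id}\n")
        fh.write(f"# replicate_id: {spec.replicate_id}\n")
        fh.write(f"# role: {spec.role}\n")
        for entry in spec.processing_log:
            fh.write(f"# log: {entry}\n")
        for m, i in zip(spec.mz.tolist(), spec.intensity.tolist()):
            fh.write(f"{m!r}{delim}{i!r}\n")


# ---------------------------------------------------------------------------
# minimal mzML

_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="{run_id}">
    <spectrumList count="1">
      <spectrum index="0" id="{spec_id}" defaultArrayLength="{n}">
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def _write_mzml(spec: Spectrum, path: Path) -> None:
    mz_b64 = base64.b64encode(np.asarray(spec.mz, "<f8").tobytes()).decode()
    int_b64 = base64.b64encode(np.asarray(spec.intensity, "<f8").tobytes()).decode()
    spec_id = xml.sax.saxutils.escape(
        f"sample={spec.sample_id} replicate={spec.replicate_id} role={spec.role}"
    )
    with open(path, "w") as fh:
        fh.write(_MZML_TEMPLATE.format(
            run_id="painprint_export", spec_id=spec_id, n=len(spec),
            mz_len=len(mz_b64), mz_b64=mz_b64, int_len=len(int_b64), int_b64=int_b64,
        ))


def _read_mzml(path: Path) -> Spectrum:
    """Minimal-profile mzML reader: first spectrum, 32/64-bit float arrays,
    uncompressed or zlib."""
    import xml.etree.ElementTree as ET
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SpectrumParseError(f"{path}: not well-formed XML ({exc})") from None
    spectrum = root.find(f".//{ns}spectrum")
    if spectrum is None:
        spectrum = root.find(".//spectrum")   # tolerate missing namespace
        ns = "" if spectrum is not None else ns
    if spectrum is None:
        raise SpectrumParseError(f"{path}: no spectrum element")
    arrays: dict[str, np.ndarray] = {}
    for bda in spectrum.iter(f"{ns}binaryDataArray"):
        acc = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
        binary = bda.find(f"{ns}binary")
        raw = base64.b64decode(binary.text or "") if binary is not None else b""
        if "MS:1000574" in acc:               # zlib compression
            raw = zlib.decompress(raw)
        dtype = "<f4" if "MS:1000521" in acc else "<f8"
        arr = np.frombuffer(raw, dtype=dtype).astype(float)
        if "MS:1000514" in acc:
            arrays["mz"] = arr
        elif "MS:1000515" in acc:
            arrays["intensity"] = arr
    if "mz" not in arrays or "intensity" not in arrays:
        raise SpectrumParseError(f"{path}: missing m/z or intensity array")
    meta = {"sample_id": "", "replicate_id": 1, "role": "sample"}
    for tok in (spectrum.get("id") or "").split():
        key, _, val = tok.partition("=")
        if key == "sample":
            meta["sample_id"] = val
        elif key == "replicate" and val.isdigit():
            meta["replicate_id"] = int(val)
        elif key == "role" and val in ("sample", "matrix_blank"):
            meta["role"] = val
    return Spectrum(mz=arrays["mz"], intensity=arrays["intensity"], **meta)


# ---------------------------------------------------------------------------
# public API

def read_spectrum(path: str | Path, format: str = "delimited") -> Spectrum:
    """Read and validate one spectrum.

    Parameters
    ----------
    path
        Input file.
    format
        ``"delimited"`` (CSV/TSV autodetected) or ``"mzml"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_delimited(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown format {format!r}")


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str = "delimited") -> Path:
    """Write a spectrum so that :func:`read_spectrum` reproduces it exactly
    (delimited) or to 64-bit float precision (mzML)."""
    if not isinstance(spectrum, Spectrum):
        raise SpectrumValidationError("write_spectrum expects a Spectrum")
    path = Path(path)
    if format == "delimited":
        _write_delimited(spectrum, path)
    elif format == "mzml":
        _write_mzml(spectrum, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
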