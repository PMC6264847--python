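"""Reading and writing of spectra, peak lists, similarity matrices and trees.

All m/z values are treated as singly protonated species in daltons; intact-cell
MALDI of proteins in this mass range yields predominantly [M+H]+ ions and
instruments are calibrated on average masses, so no charge deconvolution is
attempted.
"""

from __future__ import annotations

import base64
import re
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed on-disk representation."""


class EmptyInputError(ValueError):
    """A reader received a file or collection with no usable content."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One acquired mass spectrum (profile trace or centroided sticks).

    ``mz`` is strictly increasing and the intensity array is the same length;
    both invariants are enforced at construction time.  ``mode`` records
    whether the trace is a continuous profile or a centroided line spectrum.
    """

    sample_id: str
    replicate_id: str
    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "profile"  # "profile" | "centroid"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.size < 1:
            raise ValueError("spectrum needs at least one point")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if self.mode not in ("profile", "centroid"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class PeakList:
    """Centroided peaks of a single replicate: (m/z, intensity, SNR) triples."""

    sample_id: str
    replicate_id: str
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.mz.shape == self.intensity.shape == self.snr.shape):
            raise ValueError("mz, intensity and snr must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z values must be strictly increasing")
        if np.any(self.intensity < 0) or np.any(self.snr < 0):
            raise ValueError("intensities and SNR must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


def _sorted_unique(mz: np.ndarray, intensity: np.ndarray):
    """Sort by m/z and merge exact duplicates by summing intensity.

    Summation preserves total ion signal and restores strict monotonicity.
    """
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size == mz.size:
        return mz, intensity
    summed = np.zeros(uniq.size)
    np.add.at(summed, inverse, intensity)
    return uniq, summed


# ---------------------------------------------------------------------------
# Two-column TXT spectra (acquisition-software exports)
# ---------------------------------------------------------------------------

_SEP_RE = re.compile(r"[\s,;]+")

# Exported profile traces have thousands of grid points; exported peak lists
# rarely exceed a few hundred.  The cut-off only sets the default mode.
CENTROID_POINT_THRESHOLD = 2000


def read_spectrum_txt(path, sample_id: str, replicate_id: str,
                      mode: str | None = None) -> Spectrum:
    """Read a two-column (m/z, intensity) text export of one spectrum.

    Blank lines and ``#`` comments are skipped; whitespace, comma and
    semicolon separators are all accepted since vendor exports vary.  Rows are
    sorted on load and duplicate m/z values merged by intensity summation.
    When ``mode`` is not given it is inferred from the point count.
    """
    mz, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in _SEP_RE.split(line) if f]
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            try:
                mz.append(float(fields[0]))
                inten.append(float(fields[1]))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric field") from None
    if not mz:
        raise EmptyInputError(f"{path}: no data lines")
    mz_arr, int_arr = _sorted_unique(np.array(mz), np.array(inten))
    if mode is None:
        mode = "centroid" if mz_arr.size < CENTROID_POINT_THRESHOLD else "profile"
    return Spectrum(sample_id=sample_id, replicate_id=replicate_id,
                    mz=mz_arr, intensity=int_arr, mode=mode)


# ---------------------------------------------------------------------------
# Peak-list CSV
# ---------------------------------------------------------------------------

PEAKLIST_COLUMNS = ("mz", "intensity", "snr")


def write_peaklist_csv(pl: PeakList, path) -> None:
    df = pd.DataFrame({"mz": pl.mz, "intensity": pl.intensity, "snr": pl.snr})
    df.to_csv(path, index=False, float_format="%.4f")


def read_peaklist_csv(path, sample_id: str = "", replicate_id: str = "") -> PeakList:
    df = pd.read_csv(path)
    missing = [c for c in PEAKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df.sort_values("mz", kind="stable")
    return PeakList(sample_id=sample_id, replicate_id=replicate_id,
                    mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy(),
                    snr=df["snr"].to_numpy())


# ---------------------------------------------------------------------------
# Similarity-matrix CSV
# ---------------------------------------------------------------------------

def write_matrix_csv(sample_ids, scores, path) -> None:
    """First row/column are sample ids, entries to one decimal place."""
    df = pd.DataFrame(np.asarray(scores, dtype=float),
                      index=list(sample_ids), columns=list(sample_ids))
    df.to_csv(path, float_format="%.1f")


def read_matrix_csv(path):
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column sample ids differ")
    return list(df.index), df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_ACC_MZ = "MS:1000514"
_ACC_INTENSITY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array accession, values)."""
    kind = None
    dtype = "<f8"
    compressed = False
    payload = ""
    for child in bda.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc in (_ACC_MZ, _ACC_INTENSITY):
                kind = acc
            elif acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_F64:
                dtype = "<f8"
            elif acc == _ACC_ZLIB:
                compressed = True
        elif tag == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[Spectrum]:
    """Read MS1 spectra from an mzML file (one Spectrum per entry).

    A small namespace-agnostic parser covering the standard encodings
    (base64 32/64-bit floats, optional zlib).  Sample id defaults to the
    run id; replicate ids are the spectrum indices.
    """
    import xml.etree.ElementTree as ET
    spectra = []
    run_id = "run"
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    if _local(root.tag) not in ("mzML", "indexedmzML"):
        raise FormatError(f"{path}: not an mzML document")
    for elem in root.iter():
        if _local(elem.tag) == "run":
            run_id = elem.get("id", "run")
            break
    for i, spec_el in enumerate(e for e in root.iter()
                                if _local(e.tag) == "spectrum"):
        mode = None
        for child in spec_el:
            if _local(child.tag) == "cvParam":
                if child.get("accession") == _ACC_CENTROID:
                    mode = "centroid"
                elif child.get("accession") == _ACC_PROFILE:
                    mode = "profile"
        mz = inten = None
        for bda in (e for e in spec_el.iter()
                    if _local(e.tag) == "binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind == _ACC_MZ:
                mz = values
            elif kind == _ACC_INTENSITY:
                inten = values
        if mz is None or inten is None or mz.size == 0:
            continue
        if mz.size != inten.size:
            raise FormatError(f"{path}: spectrum {i}: array length mismatch")
        mz, inten = _sorted_unique(mz, np.clip(inten, 0.0, None))
        if mode is None:
            mode = "centroid" if mz.size < CENTROID_POINT_THRESHOLD else "profile"
        spectra.append(Spectrum(sample_id=run_id, replicate_id=str(i),
                                mz=mz, intensity=inten, mode=mode))
    return spectra


def _b64_floats(values: np.ndarray, compress: bool) -> tuple[str, int]:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii"), len(raw)


def write_mzml(spectra: list[Spectrum], path, run_id: str | None = None) -> None:
    """Write spectra as a minimal but standard-conformant mzML 1.1.0 document.

    Arrays are stored as uncompressed base64 little-endian 64-bit floats with
    the usual controlled-vocabulary accessions, which any mzML reader accepts.
    """
    if run_id is None:
        run_id = spectra[0].sample_id if spectra else "run"
    parts = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>')
    parts.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">')
    parts.append('<cvList count="1">'
                 '<cv id="MS" fullName="PSI-MS" '
                 'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
                 '</cvList>')
    parts.append('<fileDescription><fileContent>'
                 '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
                 '</fileContent></fileDescription>')
    parts.append('<softwareList count="1">'
                 '<software id="icmaldi" version="0.1.0">'
                 '<cvParam cvRef="MS" accession="MS:1000799" '
                 'name="custom unreleased software tool" value="icmaldi"/>'
                 '</software></softwareList>')
    parts.append(
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1">'
        '<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>'
        '</instrumentConfiguration></instrumentConfigurationList>')
    parts.append('<dataProcessingList count="1">'
                 '<dataProcessing id="export">'
                 '<processingMethod order="1" softwareRef="icmaldi">'
                 '<cvParam cvRef="MS" accession="MS:1000544" '
                 'name="Conversion to mzML" value=""/>'
                 '</processingMethod></dataProcessing></dataProcessingList>')
    parts.append(f'<run id="{run_id}" defaultInstrumentConfigurationRef="IC1">')
    parts.append(f'<spectrumList count="{len(spectra)}" '
                 'defaultDataProcessingRef="export">')
    for i, s in enumerate(spectra):
        mz_b64, mz_len = _b64_floats(s.mz, compress=False)
        int_b64, int_len = _b64_floats(s.intensity, compress=False)
        mode_cv = ('<cvParam cvRef="MS" accession="MS:1000127" '
                   'name="centroid spectrum" value=""/>'
                   if s.mode == "centroid" else
                   '<cvParam cvRef="MS" accession="MS:1000128" '
                   'name="profile spectrum" value=""/>')
        parts.append(
            f'<spectrum index="{i}" id="sample={s.sample_id} '
            f'replicate={s.replicate_id}" defaultArrayLength="{len(s)}">'
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            + mode_cv +
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<binary>{mz_b64}</binary></binaryDataArray>'
            f'<binaryDataArray encodedLength="{len(int_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
            f'<binary>{int_b64}</binary></binaryDataArray>'
            '</binaryDataArrayList></spectrum>')
    parts.append('</spectrumList></run></mzML>')
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
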