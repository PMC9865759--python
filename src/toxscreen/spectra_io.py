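"""Acquired-run data model and mzML input/output.

Runs are lists of centroided scans.  Retention time is stored in **seconds**
internally; conversions to the minutes printed in reports happen only at I/O
and report boundaries.  The engine's contract is centroid-only: profile-mode
spectra are rejected on read rather than centroided.

Writing emits a minimal, standard-conformant mzML 1.1 document (64-bit
little-endian, uncompressed binary arrays).  Reading is a streaming parser
over the mzML spectrum list that understands the controlled-vocabulary
terms this engine needs — ms level, polarity, centroid/profile mode, scan
start time (minutes or seconds), selected-ion m/z, collision energy — and
both 32- and 64-bit, zlib-compressed or plain binary arrays.
"""

from __future__ import annotations

import base64
import gzip
import struct
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
from xml.etree import ElementTree
from xml.sax.saxutils import escape, quoteattr

import numpy as np

__all__ = [
    "MassSpectrum",
    "AcquiredRun",
    "read_mzml",
    "write_mzml",
]

POSITIVE = "+"
NEGATIVE = "-"


@dataclass
class MassSpectrum:
    """One centroided scan: parallel m/z / intensity arrays plus metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int
    polarity: str
    rt: float  # seconds
    precursor_mz: Optional[float] = None
    collision_energy: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z values must be strictly increasing")
        if self.mz.size and self.mz[0] <= 0:
            raise ValueError("m/z values must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectra require a precursor_mz annotation")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def base_peak(self) -> Tuple[float, float]:
        if not self.mz.size:
            raise ValueError("empty spectrum has no base peak")
        i = int(np.argmax(self.intensity))
        return float(self.mz[i]), float(self.intensity[i])

    def approx_equal(self, other: "MassSpectrum", rtol: float = 1e-6) -> bool:
        if (
            self.ms_level != other.ms_level
            or self.polarity != other.polarity
            or self.n_peaks != other.n_peaks
        ):
            return False
        if not np.isclose(self.rt, other.rt, rtol=rtol, atol=1e-6):
            return False
        if (self.precursor_mz is None) != (other.precursor_mz is None):
            return False
        if self.precursor_mz is not None and not np.isclose(
            self.precursor_mz, other.precursor_mz, rtol=rtol
        ):
            return False
        return bool(
            np.allclose(self.mz, other.mz, rtol=rtol)
            and np.allclose(self.intensity, other.intensity, rtol=rtol, atol=1e-3)
        )


@dataclass
class AcquiredRun:
    """A time-ordered LC-HRMS acquisition (MS1 full scans + DDA MS2 scans)."""

    sample_id: str
    scans: List[MassSpectrum]
    scan_range: Tuple[float, float] = (70.0, 1000.0)
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scans must be sorted by retention time")
        lo, hi = self.scan_range
        for s in self.scans:
            if s.ms_level == 1 and s.mz.size and (s.mz[0] < lo - 1e-9 or s.mz[-1] > hi + 1e-9):
                raise ValueError("MS1 peak m/z outside the declared scan range")

    def ms1_scans(self, polarity: Optional[str] = None) -> List[MassSpectrum]:
        return [
            s
            for s in self.scans
            if s.ms_level == 1 and (polarity is None or s.polarity == polarity)
        ]

    def ms2_scans(self, polarity: Optional[str] = None) -> List[MassSpectrum]:
        return [
            s
            for s in self.scans
            if s.ms_level == 2 and (polarity is None or s.polarity == polarity)
        ]

    def approx_equal(self, other: "AcquiredRun", rtol: float = 1e-6) -> bool:
        return (
            self.sample_id == other.sample_id
            and len(self.scans) == len(other.scans)
            and all(a.approx_equal(b, rtol) for a, b in zip(self.scans, other.scans))
        )


# -- mzML writing --------------------------------------------------------------


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *values)
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: str = "") -> str:
    s = f'<cvParam cvRef="MS" accession="{accession}" name={quoteattr(name)}'
    s += f' value={quoteattr(str(value))}'
    if unit:
        unit_acc, unit_name = unit.split(";")
        s += (
            f' unitCvRef="UO" unitAccession="{unit_acc}"'
            f" unitName={quoteattr(unit_name)}"
        )
    return s + "/>"


def _binary_array(values: np.ndarray, kind: str) -> str:
    acc, name = (
        ("MS:1000514", "m/z array") if kind == "mz" else ("MS:1000515", "intensity array")
    )
    unit = (
        "MS:1000040;m/z" if kind == "mz" else "MS:1000131;number of detector counts"
    )
    payload = _b64_doubles(values)
    return (
        f'<binaryDataArray encodedLength="{len(payload)}">'
        + _cv("MS:1000523", "64-bit float")
        + _cv("MS:1000576", "no compression")
        + _cv(acc, name, unit=unit)
        + f"<binary>{payload}</binary></binaryDataArray>"
    )


def _spectrum_xml(index: int, s: MassSpectrum) -> str:
    parts = [
        f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{s.n_peaks}">'
    ]
    parts.append(_cv("MS:1000511", "ms level", str(s.ms_level)))
    parts.append(
        _cv("MS:1000579", "MS1 spectrum")
        if s.ms_level == 1
        else _cv("MS:1000580", "MSn spectrum")
    )
    parts.append(_cv("MS:1000127", "centroid spectrum"))
    parts.append(
        _cv("MS:1000130", "positive scan")
        if s.polarity == POSITIVE
        else _cv("MS:1000129", "negative scan")
    )
    parts.append(
        "<scanList count=\"1\">"
        + _cv("MS:1000795", "no combination")
        + "<scan>"
        + _cv("MS:1000016", "scan start time", repr(s.rt), unit="UO:0000010;second")
        + "</scan></scanList>"
    )
    if s.ms_level == 2:
        act = [_cv("MS:1000422", "beam-type collision-induced dissociation")]
        if s.collision_energy:
            for ce in s.collision_energy:
                act.append(
                    _cv("MS:1000045", "collision energy", repr(ce), unit="UO:0000266;electronvolt")
                )
        parts.append(
            "<precursorList count=\"1\"><precursor>"
            "<selectedIonList count=\"1\"><selectedIon>"
            + _cv("MS:1000744", "selected ion m/z", repr(s.precursor_mz), unit="MS:1000040;m/z")
            + "</selectedIon></selectedIonList>"
            + "<activation>"
            + "".join(act)
            + "</activation></precursor></precursorList>"
        )
    parts.append(
        '<binaryDataArrayList count="2">'
        + _binary_array(s.mz, "mz")
        + _binary_array(s.intensity, "intensity")
        + "</binaryDataArrayList></spectrum>"
    )
    return "".join(parts)


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
</cvList>
<fileDescription><fileContent>
<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
</fileContent></fileDescription>
<softwareList count="1"><software id="toxscreen" version="0.1.0">
<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="toxscreen"/>
</software></softwareList>
<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">
<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
</instrumentConfiguration></instrumentConfigurationList>
<dataProcessingList count="1"><dataProcessing id="DP1"><processingMethod order="1" softwareRef="toxscreen">
<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
</processingMethod></dataProcessing></dataProcessingList>
"""


def write_mzml(run: AcquiredRun, path: str) -> str:
    """Serialise a run to mzML.  ``.gz`` paths are gzip-compressed."""
    if not run.scans:
        raise ValueError("cannot write a run with no scans")
    body = [
        _MZML_HEADER,
        f"<run id={quoteattr(run.sample_id)} defaultInstrumentConfigurationRef=\"IC1\">",
        f'<spectrumList count="{len(run.scans)}" defaultDataProcessingRef="DP1">',
    ]
    body.extend(_spectrum_xml(i, s) for i, s in enumerate(run.scans))
    body.append("</spectrumList></run></mzML>")
    text = "".join(body)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write(text)
    return str(path)


# -- mzML reading --------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem: ElementTree.Element) -> Tuple[Optional[str], np.ndarray]:
    dtype = np.float64
    compressed = False
    kind = None
    payload = b""
    for child in elem.iter():
        tag = _strip_ns(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000523":
                dtype = np.float64
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary":
            payload = base64.b64decode(child.text or "")
    if compressed:
        payload = zlib.decompress(payload)
    arr = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)
    return kind, arr


def _parse_spectrum(elem: ElementTree.Element, path: str) -> MassSpectrum:
    level = 1
    polarity = POSITIVE
    rt = 0.0
    precursor = None
    energies: List[float] = []
    arrays: Dict[str, np.ndarray] = {}
    for child in elem.iter():
        tag = _strip_ns(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000128":
                raise ValueError(
                    f"{path}: profile-mode spectrum {elem.get('id')!r}; "
                    "centroid the data before screening"
                )
            if acc == "MS:1000511":
                level = int(child.get("value", "1"))
            elif acc == "MS:1000129":
                polarity = NEGATIVE
            elif acc == "MS:1000130":
                polarity = POSITIVE
            elif acc == "MS:1000016":
                rt = float(child.get("value", "0"))
                unit = (child.get("unitName") or "").lower()
                if "min" in unit:
                    rt *= 60.0
            elif acc == "MS:1000744":
                precursor = float(child.get("value"))
            elif acc == "MS:1000045":
                energies.append(float(child.get("value")))
        elif tag == "binaryDataArray":
            kind, arr = _decode_binary_array(child)
            if kind:
                arrays[kind] = arr
    mz = arrays.get("mz", np.empty(0))
    inten = arrays.get("intensity", np.empty(0))
    order = np.argsort(mz, kind="stable")
    return MassSpectrum(
        mz=mz[order],
        intensity=inten[order],
        ms_level=level,
        polarity=polarity,
        rt=rt,
        precursor_mz=precursor,
        collision_energy=tuple(energies) or None,
    )


def read_mzml(path: str, sample_id: Optional[str] = None) -> AcquiredRun:
    """Read a centroided mzML file into an :class:`AcquiredRun`.

    Profile-mode spectra are rejected: downstream processing operates on
    detected (centroided) ions only.  ``.gz`` paths are handled
    transparently.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    scans: List[MassSpectrum] = []
    with opener(path, "rb") as fh:
        try:
            context = ElementTree.iterparse(fh, events=("end",))
            for _, elem in context:
                tag = _strip_ns(elem.tag)
                if tag == "spectrum":
                    scans.append(_parse_spectrum(elem, str(path)))
                    elem.clear()
        except ElementTree.ParseError as exc:
            raise ValueError(f"{path}: malformed mzML ({exc})") from None
    if not scans:
        raise ValueError(f"{path}: no spectra found")
    if sample_id is None:
        sample_id = str(path).rsplit("/", 1)[-1]
        for suffix in (".gz", ".mzML", ".mzml"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
    lo = min((s.mz[0] for s in scans if s.ms_level == 1 and s.mz.size), default=70.0)
    hi = max((s.mz[-1] for s in scans if s.ms_level == 1 and s.mz.size), default=1000.0)
    return AcquiredRun(
        sample_id=sample_id,
        scans=scans,
        scan_range=(min(70.0, lo), max(1000.0, hi)),
    )
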