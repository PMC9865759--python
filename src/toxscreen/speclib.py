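"""Spectral-library data model, MSP / JSON I/O, and the built-in fixture.

A library entry is one compound's identification reference: formula,
polarity, protonated/deprotonated precursor m/z, retention time (optional),
a formula-derived isotope pattern, and an HR-MS/MS reference spectrum stored
as relative intensities with the base peak at 100.

The canonical on-disk format is a JSON dialect with explicit fields (MSP has
no standard slot for isotope patterns); NIST-style MSP text is supported for
interchange.  MSP records that cannot be parsed are routed to a rejects
report rather than silently dropped.

The built-in fixture library contains the twelve isomeric compounds used to
demonstrate isomer discrimination: six pairs sharing an exact precursor m/z,
each with retention time, the precursor survivor's relative abundance and
the five most essential fragment ions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import chem
from .chem import IsotopePattern, MolecularFormula, adduct_mz, isotope_pattern, parse_formula
from .spectra_io import MassSpectrum, NEGATIVE, POSITIVE

__all__ = [
    "LibraryEntry",
    "SpectralLibrary",
    "MspReject",
    "read_msp",
    "write_msp",
    "read_json",
    "write_json",
    "build_fixture_library",
]

PRECURSOR_CONSISTENCY_PPM = 5.0


@dataclass
class LibraryEntry:
    name: str
    formula: MolecularFormula
    polarity: str  # '+' or '-'
    precursor_mz: float
    rt: Optional[float]  # seconds; None = not defined ("ignore if not defined")
    isotope_pattern: IsotopePattern
    ms2: MassSpectrum  # relative intensities, base peak 100

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        expected = adduct_mz(self.formula, self.polarity)
        lo, hi = chem.ppm_window(expected, PRECURSOR_CONSISTENCY_PPM)
        if not (lo <= self.precursor_mz <= hi):
            raise ValueError(
                f"{self.name}: precursor_mz {self.precursor_mz} is more than "
                f"{PRECURSOR_CONSISTENCY_PPM} ppm from the computed adduct m/z {expected:.5f}"
            )
        if self.rt is not None and self.rt < 0:
            raise ValueError(f"{self.name}: negative retention time")
        rel = self.ms2.intensity
        if not rel.size:
            raise ValueError(f"{self.name}: empty reference MS2 spectrum")
        if abs(rel.max() - 100.0) > 1e-6 or rel.min() <= 0:
            raise ValueError(
                f"{self.name}: MS2 relative intensities must lie in (0, 100] with base 100"
            )

    @property
    def adduct(self) -> str:
        return "[M+H]+" if self.polarity == POSITIVE else "[M-H]-"


@dataclass
class MspReject:
    record: str
    reason: str


class SpectralLibrary:
    """An indexed collection of library entries with unique names."""

    def __init__(self, entries: Sequence[LibraryEntry], rejects: Sequence[MspReject] = ()):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate entry names: {dupes}")
        self.entries: List[LibraryEntry] = list(entries)
        self.rejects: List[MspReject] = list(rejects)
        self._index: Dict[str, Tuple[np.ndarray, List[LibraryEntry]]] = {}
        for pol in (POSITIVE, NEGATIVE):
            sub = sorted(
                (e for e in self.entries if e.polarity == pol),
                key=lambda e: e.precursor_mz,
            )
            self._index[pol] = (np.array([e.precursor_mz for e in sub]), sub)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def candidates(self, mz: float, tol_ppm: float, polarity: str) -> List[LibraryEntry]:
        """Entries whose precursor m/z lies within ``tol_ppm`` of ``mz``."""
        mzs, subs = self._index[polarity]
        lo, hi = chem.ppm_window(mz, tol_ppm)
        i, j = np.searchsorted(mzs, [lo, hi])
        return subs[int(i): int(j)]

    def polarities(self) -> List[str]:
        return sorted({e.polarity for e in self.entries}, reverse=True)


# -- reference-spectrum construction ------------------------------------------


def _make_reference_ms2(
    precursor_mz: float, peaks: Sequence[Tuple[float, float]], polarity: str
) -> MassSpectrum:
    arr = sorted(peaks)
    mz = np.array([p[0] for p in arr])
    rel = np.array([p[1] for p in arr])
    rel = 100.0 * rel / rel.max()
    return MassSpectrum(
        mz=mz,
        intensity=rel,
        ms_level=2,
        polarity=polarity,
        rt=0.0,
        precursor_mz=precursor_mz,
    )


def make_entry(
    name: str,
    formula: "MolecularFormula | str",
    polarity: str,
    rt_min: Optional[float],
    precursor_mz: Optional[float] = None,
    ms2_peaks: Sequence[Tuple[float, float]] = (),
) -> LibraryEntry:
    """Convenience constructor: RT in minutes, isotope pattern from formula."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if precursor_mz is None:
        precursor_mz = adduct_mz(formula, polarity)
    pattern = isotope_pattern(formula).shifted(
        chem.PROTON_MASS if polarity == POSITIVE else -chem.PROTON_MASS
    )
    return LibraryEntry(
        name=name,
        formula=formula,
        polarity=polarity,
        precursor_mz=float(precursor_mz),
        rt=None if rt_min is None else float(rt_min) * 60.0,
        isotope_pattern=pattern,
        ms2=_make_reference_ms2(float(precursor_mz), ms2_peaks, polarity),
    )


# -- the in-package fixture: six isomer pairs ---------------------------------
# (name, formula, RT min, precursor m/z, precursor survivor rel. abundance,
#  five fragment ions as (m/z, rel. abundance)); base peak of each spectrum
# is 100 with the survivor included as a regular peak.

_FIXTURE_ROWS = [
    ("O-Demethylvenlafaxine", "C16H25NO2", 4.13, 264.19581, 23.2,
     [(58.06605, 100.0), (246.1852, 13.6), (107.04956, 11.9), (133.06494, 5.6), (201.1275, 3.0)]),
    ("Tramadol", "C16H25NO2", 4.42, 264.19581, 10.5,
     [(58.06595, 100.0), (182.9018, 0.9), (246.1843, 0.4), (265.1989, 0.4), (56.0503, 0.2)]),
    ("MDEA", "C12H17NO2", 3.79, 208.13321, 15.2,
     [(163.07542, 100.0), (135.04408, 33.4), (133.06488, 31.4), (105.07027, 31.3), (72.08154, 9.5)]),
    ("MBDB", "C12H17NO2", 4.01, 208.13321, 8.2,
     [(135.04413, 100.0), (177.09102, 12.8), (147.08046, 8.1), (72.08154, 7.8), (136.0475, 5.3)]),
    ("Acepromazine", "C19H22N2OS", 6.02, 327.15256, 50.2,
     [(86.09708, 100.0), (58.06606, 73.3), (254.06337, 8.5), (239.0765, 4.0), (222.0916, 3.6)]),
    ("Aceprometazine", "C19H22N2OS", 5.94, 327.15256, 14.8,
     [(86.09696, 100.0), (240.04727, 20.3), (71.07362, 6.8), (239.07614, 5.8), (89.0602, 2.5)]),
    ("Morphine", "C17H19NO3", 1.27, 286.14377, 100.0,
     [(201.09116, 6.9), (229.08565, 4.5), (183.08067, 3.4), (185.05997, 3.1), (211.07568, 3.0)]),
    ("Norcodeine", "C17H19NO3", 2.95, 286.14377, 100.0,
     [(268.13263, 10.7), (215.10689, 6.5), (225.09088, 5.4), (121.06505, 5.3), (243.10130, 4.7)]),
    ("6-MAM", "C19H21NO4", 3.56, 328.15433, 100.0,
     [(211.07524, 13.1), (165.06987, 7.5), (193.06425, 7.0), (58.06528, 6.0), (183.08049, 4.5)]),
    ("Naloxone", "C19H21NO4", 3.11, 328.15433, 75.4,
     [(310.1438, 100.0), (253.10934, 22.3), (268.13297, 19.5), (311.14734, 11.6), (269.1049, 10.3)]),
    ("N-Demethylclobazam", "C15H11ClN2O2", 6.42, 287.05818, 29.2,
     [(245.04753, 100.0), (210.07864, 13.7), (241.05254, 12.4), (269.0474, 4.8), (246.0511, 2.7)]),
    ("Oxazepam", "C15H11ClN2O2", 6.40, 287.05818, 40.4,
     [(241.05254, 100.0), (269.04745, 40.9), (104.04984, 17.6), (231.06830, 15.3), (128.02629, 8.7)]),
]

ISOMER_PAIRS = [
    ("O-Demethylvenlafaxine", "Tramadol"),
    ("MDEA", "MBDB"),
    ("Acepromazine", "Aceprometazine"),
    ("Morphine", "Norcodeine"),
    ("6-MAM", "Naloxone"),
    ("N-Demethylclobazam", "Oxazepam"),
]


def build_fixture_library() -> SpectralLibrary:
    """The twelve-compound isomer-pair reference library (positive mode)."""
    entries = []
    for name, formula, rt_min, prec_mz, prec_rel, frags in _FIXTURE_ROWS:
        peaks = list(frags) + [(prec_mz, prec_rel)]
        entries.append(
            make_entry(name, formula, POSITIVE, rt_min, prec_mz, peaks)
        )
    return SpectralLibrary(entries)


# -- MSP I/O -------------------------------------------------------------------


def _parse_msp_record(block: str) -> LibraryEntry:
    meta: Dict[str, str] = {}
    peak_lines: List[str] = []
    num_peaks: Optional[int] = None
    in_peaks = False
    for line in block.splitlines():
        line = line.strip()
        if not line:
            continue
        if not in_peaks and ":" in line:
            key, _, val = line.partition(":")
            key = key.strip().lower().replace(" ", "")
            meta[key] = val.strip()
            if key == "numpeaks":
                num_peaks = int(val)
                in_peaks = True
        elif in_peaks:
            peak_lines.append(line)
        else:
            raise ValueError(f"unparseable line before Num Peaks: {line!r}")
    if "name" not in meta:
        raise ValueError("record has no Name field")
    if num_peaks is None:
        raise ValueError("record has no Num Peaks field")
    if "formula" not in meta:
        raise ValueError("record has no Formula field")
    peaks: List[Tuple[float, float]] = []
    for line in peak_lines:
        cols = line.replace(";", " ").split()
        if len(cols) < 2:
            raise ValueError(f"malformed peak line: {line!r}")
        peaks.append((float(cols[0]), float(cols[1])))
    if len(peaks) != num_peaks:
        raise ValueError(f"Num Peaks says {num_peaks} but {len(peaks)} peaks present")
    if not peaks:
        raise ValueError("record has no peaks")
    formula = parse_formula(meta["formula"])
    pol_txt = meta.get("polarity", meta.get("ionmode", "positive")).lower()
    polarity = NEGATIVE if pol_txt.startswith("n") else POSITIVE
    precursor = float(meta["precursormz"]) if "precursormz" in meta else None
    rt_min = float(meta["rt"]) if "rt" in meta else None
    return make_entry(meta["name"], formula, polarity, rt_min, precursor, peaks)


def read_msp(path: str) -> SpectralLibrary:
    """Read a NIST-dialect MSP file.

    Unparseable records are collected on the returned library's ``rejects``
    list (record text + reason); the file fails only if *no* record parses.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    blocks = [b for b in text.replace("\r\n", "\n").split("\n\n") if b.strip()]
    entries: List[LibraryEntry] = []
    rejects: List[MspReject] = []
    for block in blocks:
        try:
            entries.append(_parse_msp_record(block))
        except (ValueError, chem.FormulaError) as exc:
            rejects.append(MspReject(record=block, reason=str(exc)))
    if not entries:
        raise ValueError(f"{path}: no parseable MSP records")
    return SpectralLibrary(entries, rejects)


def write_msp(lib: SpectralLibrary, path: str) -> str:
    """Write entries as NIST-dialect MSP.  Undefined RT omits the RT field."""
    records = []
    for e in lib.entries:
        lines = [
            f"Name: {e.name}",
            f"Formula: {e.formula.to_string()}",
            f"Polarity: {'Positive' if e.polarity == POSITIVE else 'Negative'}",
            f"PrecursorMZ: {e.precursor_mz:.5f}",
        ]
        if e.rt is not None:
            lines.append(f"RT: {e.rt / 60.0:.6g}")
        lines.append(f"Num Peaks: {e.ms2.n_peaks}")
        lines.extend(
            f"{mz:.5f} {inten:.6g}" for mz, inten in zip(e.ms2.mz, e.ms2.intensity)
        )
        records.append("\n".join(lines))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n\n".join(records) + "\n")
    return str(path)


def write_rejects_tsv(lib: SpectralLibrary, path: str) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reason\trecord\n")
        for r in lib.rejects:
            fh.write(f"{r.reason}\t{r.record.replace(chr(10), ' | ')}\n")
    return str(path)


# -- canonical JSON dialect ----------------------------------------------------


def _entry_to_dict(e: LibraryEntry) -> dict:
    return {
        "name": e.name,
        "formula": e.formula.to_string(),
        "polarity": e.polarity,
        "precursor_mz": e.precursor_mz,
        "rt_s": e.rt,
        "isotope_pattern": [list(p) for p in e.isotope_pattern.peaks],
        "ms2": [[float(m), float(i)] for m, i in zip(e.ms2.mz, e.ms2.intensity)],
    }


def _entry_from_dict(d: dict) -> LibraryEntry:
    formula = parse_formula(d["formula"])
    polarity = d["polarity"]
    pattern = IsotopePattern(tuple((m, r) for m, r in d["isotope_pattern"]))
    return LibraryEntry(
        name=d["name"],
        formula=formula,
        polarity=polarity,
        precursor_mz=float(d["precursor_mz"]),
        rt=None if d.get("rt_s") is None else float(d["rt_s"]),
        isotope_pattern=pattern,
        ms2=_make_reference_ms2(float(d["precursor_mz"]), d["ms2"], polarity),
    )


def write_json(lib: SpectralLibrary, path: str) -> str:
    doc = {
        "format": "toxscreen-library",
        "version": 1,
        "entries": [_entry_to_dict(e) for e in lib.entries],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
    return str(path)


def read_json(path: str) -> SpectralLibrary:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "toxscreen-library":
        raise ValueError(f"{path}: not a toxscreen library file")
    return SpectralLibrary([_entry_from_dict(d) for d in doc["entries"]])
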