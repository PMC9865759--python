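"""Molecular-formula arithmetic for high-resolution mass spectrometry.

Accurate masses and isotopic abundances come from an embedded, versioned
element table (CIAAW representative isotopic composition).  Protonation and
deprotonation use the proton mass (1.00727646677 Da), not the hydrogen-atom
mass, so that computed [M+H]+ / [M-H]- m/z values agree with instrument
software to the fifth decimal place.

Only singly charged, +-H adducts are supported: electrospray screening of
small-molecule drugs overwhelmingly observes [M+H]+ in positive mode and
[M-H]- in negative mode.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, List, Mapping, Tuple

__all__ = [
    "PROTON_MASS",
    "ELEMENT_TABLE_VERSION",
    "MolecularFormula",
    "IsotopePattern",
    "Adduct",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_window",
    "isotope_pattern",
]


def _load_element_table() -> tuple[str, float, Dict[str, List[Tuple[float, float]]]]:
    text = resources.files("toxscreen.data").joinpath("elements.json").read_text()
    raw = json.loads(text)
    table = {
        sym: [(float(m), float(a)) for m, a in isotopes]
        for sym, isotopes in raw["elements"].items()
    }
    return raw["version"], float(raw["proton_mass_da"]), table


ELEMENT_TABLE_VERSION, PROTON_MASS, _ISOTOPES = _load_element_table()

#: most abundant isotope mass per element, used for monoisotopic masses
_PRINCIPAL_MASS: Dict[str, float] = {
    sym: max(isos, key=lambda t: t[1])[0] for sym, isos in _ISOTOPES.items()
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map, e.g. ``{"C": 16, "H": 25, "N": 1, "O": 2}``.

    Element symbols must appear in the embedded isotope table; counts are
    strictly positive.  Deuterium is written with the explicit token ``D``.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("formula must contain at least one atom")
        for sym, n in self.counts.items():
            if sym not in _ISOTOPES:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts.items())

    def to_string(self) -> str:
        """Hill-order string (C, H, then alphabetical)."""
        symbols = sorted(
            self.counts,
            key=lambda s: (s not in ("C", "H"), s != "C", s != "H", s),
        )
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] > 1 else s for s in symbols
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated (unit-mass-binned) isotopologue distribution.

    ``peaks`` holds ``(mz, relative_intensity)`` pairs sorted by m/z with the
    base peak at 100.  ``resolution_fwhm`` records the resolving power the
    aggregation is meant for (coarse patterns; fine structure unresolved).
    """

    peaks: Tuple[Tuple[float, float], ...]
    resolution_fwhm: float = 35000.0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("isotope pattern must contain at least one peak")
        mzs = [p[0] for p in self.peaks]
        if sorted(mzs) != mzs:
            raise ValueError("isotope pattern peaks must be sorted by m/z")
        rels = [p[1] for p in self.peaks]
        if abs(max(rels) - 100.0) > 1e-9:
            raise ValueError("base peak relative intensity must equal 100")
        if any(r <= 0 or r > 100.0 + 1e-9 for r in rels):
            raise ValueError("relative intensities must lie in (0, 100]")
        object.__setattr__(self, "peaks", tuple((float(m), float(r)) for m, r in self.peaks))

    def shifted(self, delta_mz: float) -> "IsotopePattern":
        """Pattern translated along the m/z axis (e.g. by a proton mass)."""
        return IsotopePattern(
            tuple((m + delta_mz, r) for m, r in self.peaks), self.resolution_fwhm
        )


@dataclass(frozen=True)
class Adduct:
    """A charge-carrying modification of the neutral molecule."""

    name: str
    charge_sign: int
    mass_delta: float


ADDUCTS: Dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, +PROTON_MASS),
    "[M-H]-": Adduct("[M-H]-", -1, -PROTON_MASS),
}
# unicode minus variants accepted on lookup
_ADDUCT_ALIASES = {
    "[M−H]−": "[M-H]-",
    "[M−H]-": "[M-H]-",
    "+": "[M+H]+",
    "-": "[M-H]-",
}


def _resolve_adduct(a: "Adduct | str") -> Adduct:
    if isinstance(a, Adduct):
        return a
    key = _ADDUCT_ALIASES.get(a, a)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise ValueError(f"unsupported adduct: {a!r}") from None


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count string such as ``"C15H11ClN2O2"``.

    The grammar is a flat sequence of element tokens with optional counts
    (Hill notation or any other order); no parentheses, charges or isotope
    brackets.  Deuterated positions use the ``D`` token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in _ISOTOPES:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: "MolecularFormula | str") -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(_PRINCIPAL_MASS[sym] * n for sym, n in f.counts.items())


def adduct_mz(f: "MolecularFormula | str", adduct: "Adduct | str") -> float:
    """m/z of the (singly charged) adduct ion of formula ``f``."""
    a = _resolve_adduct(adduct)
    return monoisotopic_mass(f) + a.mass_delta


def ppm_window(mz: float, tol_ppm: float) -> Tuple[float, float]:
    """Symmetric relative mass-tolerance window ``mz * (1 +- tol*1e-6)``."""
    if mz <= 0:
        raise ValueError(f"mz must be positive, got {mz}")
    if tol_ppm < 0:
        raise ValueError(f"tolerance must be non-negative, got {tol_ppm}")
    half = mz * tol_ppm * 1e-6
    return (mz - half, mz + half)


# -- isotope pattern ----------------------------------------------------------

_PRUNE_ABUNDANCE = 1e-10
_MERGE_DECIMALS = 6


def _convolve(a: Dict[float, float], b: Dict[float, float]) -> Dict[float, float]:
    out: Dict[float, float] = {}
    for m1, p1 in a.items():
        for m2, p2 in b.items():
            p = p1 * p2
            if p < _PRUNE_ABUNDANCE:
                continue
            m = round(m1 + m2, _MERGE_DECIMALS)
            out[m] = out.get(m, 0.0) + p
    return out


def _element_power(sym: str, n: int) -> Dict[float, float]:
    """Isotopologue distribution of n atoms of one element (binary powering)."""
    base = {round(m, _MERGE_DECIMALS): p for m, p in _ISOTOPES[sym]}
    result: Dict[float, float] = {0.0: 1.0}
    while n:
        if n & 1:
            result = _convolve(result, base)
        n >>= 1
        if n:
            base = _convolve(base, base)
    return result


def isotope_pattern(
    f: "MolecularFormula | str",
    max_peaks: int = 8,
    min_rel_intensity: float = 0.1,
    resolution_fwhm: float = 35000.0,
) -> IsotopePattern:
    """Aggregated isotope pattern of a neutral formula.

    The full isotopologue distribution is built by convolving elemental
    isotope vectors, then collapsed to unit-mass bins (nominal-mass shifts
    from the monoisotopic peak); each bin's centroid is the abundance-weighted
    mean m/z.  Intensities are normalised to base peak 100 and truncated at
    ``max_peaks`` peaks or below ``min_rel_intensity`` percent.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    dist: Dict[float, float] = {0.0: 1.0}
    for sym, n in f.counts.items():
        dist = _convolve(dist, _element_power(sym, n))

    mono = min(dist)  # lightest isotopologue = monoisotopic
    bins: Dict[int, Tuple[float, float]] = {}  # shift -> (sum p, sum p*m)
    for m, p in dist.items():
        k = int(round(m - mono))
        sp, spm = bins.get(k, (0.0, 0.0))
        bins[k] = (sp + p, spm + p * m)

    base = max(sp for sp, _ in bins.values())
    peaks = sorted(
        (spm / sp, 100.0 * sp / base) for sp, spm in bins.values()
    )
    peaks = [(m, r) for m, r in peaks if r >= min_rel_intensity]
    if max_peaks is not None and len(peaks) > max_peaks:
        # keep the most intense ones, then restore m/z order
        keep = sorted(sorted(peaks, key=lambda t: -t[1])[:max_peaks])
        peaks = keep
    return IsotopePattern(tuple(peaks), resolution_fwhm)
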