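"""The identification engine: five criteria and the major/minor decision rule.

A compound is *identified* when all three **major** criteria hold:

1. precursor — an extracted-ion chromatogram peak at the library precursor
   m/z (+-5 ppm) with S/N >= 10;
2. fragments — at least one library fragment matched in a DDA MS2 scan
   within 10 mmu and above 5000 a.u.;
3. library match — forward search index (SI) >= 500, reverse search index
   (RSI) >= 600 and library score >= 20 against the reference spectrum.

Retention time (60 s window, "ignore if not defined") and isotope-pattern
fit (threshold 70, 5 ppm / 30% deviation tolerances) are **minor** criteria:
they are evaluated and reported but never veto an identification.

SI/RSI are match factors on a 0-999 scale computed with the classic
identity-search peak weighting (intensity^0.6 x m/z^3).  The composite score
combines the squared weighted cosine with an intensity-ratio consistency
term over adjacent matched peaks; the reverse index discards query peaks
with no counterpart in the library spectrum.  Commercial software computes
proprietary variants of these quantities — thresholds here are the
published operating points, and the formulas are fixed by this module's
tests, but score-for-score parity with any vendor tool is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import ppm_window
from .detect import ChromPeak, build_xic, detect_peaks
from .speclib import LibraryEntry, SpectralLibrary
from .spectra_io import AcquiredRun, MassSpectrum

__all__ = [
    "IdentificationSettings",
    "CriterionResult",
    "IdentificationResult",
    "match_precursor",
    "match_fragments",
    "spectral_scores",
    "match_rt",
    "isotope_fit",
    "identify",
]

MAJOR_CRITERIA = ("precursor", "fragments", "library_match")
MINOR_CRITERIA = ("rt", "isotope")


@dataclass(frozen=True)
class IdentificationSettings:
    """Screening operating point (defaults are the published values)."""

    precursor_tol_ppm: float = 5.0
    fragment_tol_mmu: float = 10.0
    min_fragments: int = 1
    fragment_intensity_min: float = 5000.0
    rt_window_s: float = 60.0
    isotope_fit_min: float = 70.0
    isotope_tol_ppm: float = 5.0
    isotope_intensity_dev: float = 30.0  # percentage points
    isotope_min_rel: float = 5.0  # predicted peaks below this rel% are not required
    si_min: float = 500.0
    rsi_min: float = 600.0
    library_score_min: float = 20.0
    snr_min: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "precursor_tol_ppm",
            "fragment_tol_mmu",
            "rt_window_s",
            "isotope_tol_ppm",
            "isotope_intensity_dev",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "min_fragments",
            "fragment_intensity_min",
            "isotope_fit_min",
            "si_min",
            "rsi_min",
            "library_score_min",
            "snr_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


@dataclass
class CriterionResult:
    criterion: str
    passed: bool
    value: Optional[float] = None  # score / error in criterion-specific units
    detail: Optional[dict] = None


@dataclass
class IdentificationResult:
    entry: LibraryEntry
    sample_id: str
    criteria: Dict[str, CriterionResult]
    major_pass: bool
    minor_pass: bool
    identified: bool
    rt_observed: Optional[float] = None  # seconds
    mass_error_ppm: Optional[float] = None
    si: Optional[int] = None
    rsi: Optional[int] = None

    def to_record(self) -> dict:
        rec = {
            "compound": self.entry.name,
            "sample_id": self.sample_id,
            "identified": self.identified,
            "major_pass": self.major_pass,
            "minor_pass": self.minor_pass,
            "rt_observed_min": None
            if self.rt_observed is None
            else round(self.rt_observed / 60.0, 4),
            "mass_error_ppm": None
            if self.mass_error_ppm is None
            else round(self.mass_error_ppm, 3),
            "si": self.si,
            "rsi": self.rsi,
        }
        for name, c in self.criteria.items():
            rec[f"{name}_pass"] = c.passed
            rec[f"{name}_value"] = None if c.value is None else round(c.value, 4)
        return rec


# -- criterion 1: precursor presence ------------------------------------------


def match_precursor(
    run: AcquiredRun, entry: LibraryEntry, s: IdentificationSettings
) -> CriterionResult:
    """XIC peak at the precursor m/z with S/N >= threshold."""
    try:
        xic = build_xic(run, entry.precursor_mz, s.precursor_tol_ppm, entry.polarity)
        peaks = detect_peaks(xic, snr_min=s.snr_min)
    except ValueError:
        peaks = []
    if not peaks:
        return CriterionResult("precursor", False, detail={"peaks": []})
    if entry.rt is not None:
        # isomers share the exact precursor m/z: prefer the XIC peak eluting
        # at the entry's own retention time over a taller co-isomer peak
        best = min(peaks, key=lambda p: (abs(p.rt_apex - entry.rt), -p.height))
    else:
        best = max(peaks, key=lambda p: p.height)
    err_ppm = (
        (best.mz_observed - entry.precursor_mz) / entry.precursor_mz * 1e6
        if np.isfinite(best.mz_observed)
        else None
    )
    return CriterionResult(
        "precursor",
        True,
        value=err_ppm,
        detail={"peaks": peaks, "best": best},
    )


# -- criterion 2: fragment ions ------------------------------------------------


def _greedy_pairs(
    query_mz: np.ndarray,
    lib_mz: np.ndarray,
    tol_da: float,
    query_w: Optional[np.ndarray] = None,
    lib_w: Optional[np.ndarray] = None,
) -> List[Tuple[int, int]]:
    """Greedy nearest-m/z pairing, each peak used once.

    Candidate pairs within tolerance are taken in order of increasing m/z
    difference; ties break toward the higher intensity product.
    """
    cand = []
    for qi, qmz in enumerate(query_mz):
        lo = np.searchsorted(lib_mz, qmz - tol_da)
        hi = np.searchsorted(lib_mz, qmz + tol_da, side="right")
        for li in range(int(lo), int(hi)):
            prod = 0.0
            if query_w is not None and lib_w is not None:
                prod = float(query_w[qi] * lib_w[li])
            cand.append((abs(qmz - lib_mz[li]), -prod, qi, li))
    cand.sort()
    used_q, used_l = set(), set()
    pairs = []
    for _, _, qi, li in cand:
        if qi in used_q or li in used_l:
            continue
        used_q.add(qi)
        used_l.add(li)
        pairs.append((qi, li))
    return pairs


def _library_fragment_mask(entry: LibraryEntry, tol_da: float) -> np.ndarray:
    """True for library peaks that are fragments (not the precursor survivor)."""
    return np.abs(entry.ms2.mz - entry.precursor_mz) > 2.0 * tol_da


def match_fragments(
    ms2: MassSpectrum, entry: LibraryEntry, s: IdentificationSettings
) -> CriterionResult:
    """Count library fragments matched within 10 mmu at >= 5000 a.u."""
    tol_da = s.fragment_tol_mmu * 1e-3
    frag_mask = _library_fragment_mask(entry, tol_da)
    lib_mz = entry.ms2.mz[frag_mask]
    obs_mask = ms2.intensity >= s.fragment_intensity_min
    obs_mz = ms2.mz[obs_mask]
    obs_int = ms2.intensity[obs_mask]
    pairs = _greedy_pairs(obs_mz, lib_mz, tol_da, obs_int, entry.ms2.intensity[frag_mask])
    matched = [
        {
            "library_mz": float(lib_mz[li]),
            "observed_mz": float(obs_mz[qi]),
            "observed_intensity": float(obs_int[qi]),
            "delta_mmu": float((obs_mz[qi] - lib_mz[li]) * 1e3),
        }
        for qi, li in pairs
    ]
    n = len(matched)
    return CriterionResult(
        "fragments", n >= s.min_fragments, value=float(n), detail={"matched": matched}
    )


# -- criterion 3: library spectrum match (SI / RSI) ---------------------------


def _weights(mz: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    rel = 100.0 * intensity / intensity.max()
    return rel**0.6 * mz**3


def spectral_scores(
    query: MassSpectrum,
    entry: LibraryEntry,
    s: IdentificationSettings = IdentificationSettings(),
) -> Tuple[int, int]:
    """Forward (SI) and reverse (RSI) match factors on a 0-999 scale.

    Peaks within ``2 x fragment_tol`` of the precursor m/z are removed from
    both spectra first ("ignore precursor").  Remaining peaks are paired
    greedily within the fragment tolerance; the forward score counts every
    peak of both spectra against the match, the reverse score ignores query
    peaks absent from the library spectrum.
    """
    if query.n_peaks == 0 or entry.ms2.n_peaks == 0:
        raise ValueError("spectral_scores requires non-empty spectra")
    tol_da = s.fragment_tol_mmu * 1e-3
    prec = entry.precursor_mz

    def strip_precursor(mz, inten):
        keep = np.abs(mz - prec) > 2.0 * tol_da
        return mz[keep], inten[keep]

    qmz, qint = strip_precursor(query.mz, query.intensity)
    lmz, lint = strip_precursor(entry.ms2.mz, entry.ms2.intensity)
    if qmz.size == 0 or lmz.size == 0:
        return 0, 0
    qw = _weights(qmz, qint)
    lw = _weights(lmz, lint)

    pairs = _greedy_pairs(qmz, lmz, tol_da, qw, lw)
    if not pairs:
        return 0, 0
    pairs.sort(key=lambda p: qmz[p[0]])  # ascending m/z for the ratio term
    qi = np.array([p[0] for p in pairs])
    li = np.array([p[1] for p in pairs])

    # each matched product is damped by the pair's intensity consistency:
    # a peak at 0.4% of base matching one at 13.6% is a coincidence of m/z,
    # not of the spectrum, and must not dominate via the m/z^3 weight
    rq = 100.0 * qint / qint.max()
    rl = 100.0 * lint / lint.max()
    ratio = rq[qi] / rl[li]
    consistency = np.sqrt(np.minimum(ratio, 1.0 / ratio))
    num = float(np.dot(consistency * qw[qi], lw[li]))
    dot_fwd = num**2 / (float(np.sum(qw**2)) * float(np.sum(lw**2)))
    dot_rev = num**2 / (float(np.sum(qw[qi] ** 2)) * float(np.sum(lw**2)))

    # intensity-ratio consistency over adjacent matched peaks
    n_m = len(pairs)
    ratio_sum = 1.0
    for k in range(1, n_m):
        y = (qw[qi[k]] / qw[qi[k - 1]]) * (lw[li[k - 1]] / lw[li[k]])
        ratio_sum += min(y, 1.0 / y)
    mf_ratio = ratio_sum / n_m

    n_q = int(qmz.size)
    si = (n_q * dot_fwd + n_m * mf_ratio) / (n_q + n_m)
    rsi = (dot_rev + mf_ratio) / 2.0
    return int(round(999 * si)), int(round(999 * rsi))


# -- criterion 4: retention time ----------------------------------------------


def match_rt(
    rt_observed: Optional[float], entry: LibraryEntry, s: IdentificationSettings
) -> CriterionResult:
    """Pass when within the RT window; undefined library RT always passes."""
    if entry.rt is None:
        return CriterionResult("rt", True, detail={"library_rt": None})
    if rt_observed is None:
        return CriterionResult("rt", False, detail={"library_rt": entry.rt})
    err = abs(rt_observed - entry.rt)
    return CriterionResult(
        "rt", err <= s.rt_window_s, value=err, detail={"library_rt": entry.rt}
    )


# -- criterion 5: isotope pattern fit -----------------------------------------


def isotope_fit(
    ms1: MassSpectrum, entry: LibraryEntry, s: IdentificationSettings
) -> CriterionResult:
    """Fit score (0-100) between observed and predicted isotopologue pattern.

    Predicted peaks at >= ``isotope_min_rel`` percent are looked up within
    the isotope ppm tolerance.  Both patterns are normalised to base 100; the
    per-peak deviation in percentage points is capped at the intensity
    deviation tolerance, and the score is ``100 x (1 - mean(capped dev /
    tolerance))``.  An unmatched predicted peak contributes the full
    tolerance; an unmatched base peak zeroes the score.
    """
    predicted = [
        (m, r) for m, r in entry.isotope_pattern.peaks if r >= s.isotope_min_rel
    ]
    obs_int = []
    for m, _ in predicted:
        lo, hi = ppm_window(m, s.isotope_tol_ppm)
        i, j = np.searchsorted(ms1.mz, [lo, hi])
        obs_int.append(float(ms1.intensity[i:j].sum()) if j > i else 0.0)
    base_idx = int(np.argmax([r for _, r in predicted]))
    if obs_int[base_idx] <= 0:
        return CriterionResult("isotope", False, value=0.0)
    scale = 100.0 / obs_int[base_idx]
    tol = s.isotope_intensity_dev
    devs = []
    for (m, pred_rel), oi in zip(predicted, obs_int):
        d = abs(oi * scale - pred_rel) if oi > 0 else tol
        devs.append(min(d, tol))
    score = 100.0 * (1.0 - float(np.mean(devs)) / tol)
    return CriterionResult(
        "isotope",
        score >= s.isotope_fit_min,
        value=score,
        detail={"predicted": predicted, "observed_rel": [oi * scale for oi in obs_int]},
    )


# -- orchestration -------------------------------------------------------------


def _select_ms2_scans(
    run: AcquiredRun, entry: LibraryEntry, peak: ChromPeak, s: IdentificationSettings
) -> List[MassSpectrum]:
    lo, hi = ppm_window(entry.precursor_mz, s.precursor_tol_ppm)
    ms1 = run.ms1_scans(entry.polarity)
    pad = float(np.median(np.diff([sc.rt for sc in ms1]))) if len(ms1) > 1 else 1.0
    return [
        sc
        for sc in run.ms2_scans(entry.polarity)
        if sc.precursor_mz is not None
        and lo <= sc.precursor_mz <= hi
        and peak.rt_start - pad <= sc.rt <= peak.rt_end + pad
        and sc.n_peaks > 0
    ]


def _nearest_ms1(run: AcquiredRun, polarity: str, rt: float) -> Optional[MassSpectrum]:
    scans = run.ms1_scans(polarity)
    if not scans:
        return None
    return min(scans, key=lambda sc: abs(sc.rt - rt))


def identify(
    run: AcquiredRun,
    lib: SpectralLibrary,
    s: IdentificationSettings = IdentificationSettings(),
) -> List[IdentificationResult]:
    """Screen a run against a library; one result per library entry.

    Results are sorted identified-first, then by descending SI.  Order of
    library entries does not influence any individual result.
    """
    if len(lib) == 0:
        raise ValueError("empty library")
    results = []
    for entry in lib:
        results.append(_identify_entry(run, entry, s))
    results.sort(key=lambda r: (not r.identified, -(r.si or 0), r.entry.name))
    return results


def _identify_entry(
    run: AcquiredRun, entry: LibraryEntry, s: IdentificationSettings
) -> IdentificationResult:
    criteria: Dict[str, CriterionResult] = {}
    prec = match_precursor(run, entry, s)
    criteria["precursor"] = prec

    rt_observed = None
    mass_error = prec.value
    si = rsi = None
    if prec.passed:
        best_peak: ChromPeak = prec.detail["best"]
        rt_observed = best_peak.rt_apex
        scans = _select_ms2_scans(run, entry, best_peak, s)
        best_scan = None
        best_scores = (0, 0)
        for sc in scans:
            scores = spectral_scores(sc, entry, s)
            # highest SI wins; ties resolved toward the earlier scan
            if best_scan is None or scores[0] > best_scores[0]:
                best_scan, best_scores = sc, scores
        if best_scan is not None:
            si, rsi = best_scores
            # fragment *presence* may be confirmed by any DDA scan across the
            # chromatographic peak (the absolute 5000 a.u. floor favours scans
            # near the apex, while SI/RSI are intensity-normalised)
            frag_results = [match_fragments(sc, entry, s) for sc in scans]
            criteria["fragments"] = max(
                frag_results, key=lambda r: (r.passed, r.value or 0.0)
            )
        else:
            criteria["fragments"] = CriterionResult(
                "fragments", False, value=0.0, detail={"matched": []}
            )
        lib_ok = (
            si is not None
            and si >= s.si_min
            and rsi >= s.rsi_min
            and si >= s.library_score_min  # library score == SI surrogate
        )
        criteria["library_match"] = CriterionResult(
            "library_match", bool(lib_ok), value=None if si is None else float(si)
        )
        ms1_apex = _nearest_ms1(run, entry.polarity, best_peak.rt_apex)
        criteria["isotope"] = (
            isotope_fit(ms1_apex, entry, s)
            if ms1_apex is not None
            else CriterionResult("isotope", False, value=0.0)
        )
    else:
        criteria["fragments"] = CriterionResult("fragments", False, value=0.0)
        criteria["library_match"] = CriterionResult("library_match", False)
        criteria["isotope"] = CriterionResult("isotope", False, value=0.0)

    criteria["rt"] = match_rt(rt_observed, entry, s)

    major = all(criteria[c].passed for c in MAJOR_CRITERIA)
    minor = all(criteria[c].passed for c in MINOR_CRITERIA)
    return IdentificationResult(
        entry=entry,
        sample_id=run.sample_id,
        criteria=criteria,
        major_pass=major,
        minor_pass=minor,
        identified=major,
        rt_observed=rt_observed,
        mass_error_ppm=mass_error,
        si=si,
        rsi=rsi,
    )
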