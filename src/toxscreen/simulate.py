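"""Synthetic LC-HRMS runs with the screening method's acquisition geometry.

The simulator emulates what the identification engine consumes, not the
physics behind it: Gaussian elution profiles carrying formula-derived
isotope patterns, centroided MS1 full scans over m/z 70-1000, and a
data-dependent acquisition loop that fragments the top-3 most intense
inclusion-list ions per cycle with a 3 s dynamic exclusion.  MS2 spectra
are the library reference spectra scaled to the precursor's momentary
intensity with multiplicative log-normal noise; co-isolated compounds
within the 2 m/z isolation window contribute jointly, so closely eluting
isomers produce mixed spectra just as a real instrument would.

The response model is linear: apex MS1 intensity = concentration x
response_factor (default 1000 a.u. per ug/L, which places identification
limits at low-ug/L spikes).  Ionisation suppression or extraction losses
are represented by scaling the response factor.  Every random draw comes
from one seeded generator, so a fixed seed reproduces a run bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .speclib import LibraryEntry, SpectralLibrary
from .spectra_io import AcquiredRun, MassSpectrum, NEGATIVE, POSITIVE

__all__ = ["SpikeSpec", "SimulationConfig", "simulate_run", "dilution_series"]


@dataclass
class SpikeSpec:
    entry: LibraryEntry
    concentration: float  # ug/L
    response_factor: float = 1000.0  # a.u. per ug/L

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.response_factor <= 0:
            raise ValueError("response_factor must be positive")

    @property
    def apex_intensity(self) -> float:
        return self.concentration * self.response_factor


@dataclass(frozen=True)
class SimulationConfig:
    gradient_length: float = 915.0  # s (15.25 min acquisition)
    ms1_cycle: float = 0.5  # s between MS1 full scans
    peak_width_fwhm: float = 6.0  # s chromatographic peak width
    noise_sigma: float = 200.0  # a.u., additive Gaussian intensity noise
    baseline: float = 0.0  # a.u.
    matrix_peak_count: int = 20  # co-extracted background compounds
    matrix_intensity_median: float = 5e4  # a.u. apex (log-normal)
    noise_peaks_per_scan: int = 25
    dda_top_n: int = 3
    dynamic_exclusion_s: float = 3.0
    dda_min_intensity: float = 1000.0  # a.u. to trigger MS2
    isolation_window_mz: float = 2.0
    scan_range: Tuple[float, float] = (70.0, 1000.0)
    mz_jitter_ppm: float = 1.0  # Gaussian, truncated at 3 sigma
    ms2_noise_sigma: float = 0.05  # log-normal sigma on fragment intensities
    ms2_min_intensity: float = 100.0  # centroider floor for MS2 peaks
    ms2_yield: float = 1.0  # fragment base-peak intensity / precursor intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gradient_length <= 0 or self.ms1_cycle <= 0 or self.peak_width_fwhm <= 0:
            raise ValueError("durations must be positive")
        if self.dda_top_n < 1:
            raise ValueError("dda_top_n must be >= 1")


_MS2_SCAN_OFFSET = 0.02  # s between the MS1 scan and each dependent MS2 scan
_MIN_SIGNAL = 1.0  # a.u.; elution profile truncated below this


def _jitter_mz(rng: np.random.Generator, mz: np.ndarray, ppm: float) -> np.ndarray:
    if ppm <= 0:
        return mz
    z = np.clip(rng.standard_normal(mz.shape), -3.0, 3.0)
    return mz * (1.0 + z * ppm * 1e-6)


def _merge_sorted(mz: np.ndarray, inten: np.ndarray, tol_da: float = 2e-4):
    """Sort and merge peaks closer than ``tol_da`` (intensity-weighted m/z)."""
    if mz.size == 0:
        return mz, inten
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    out_mz: List[float] = []
    out_in: List[float] = []
    for m, i in zip(mz, inten):
        if out_mz and m - out_mz[-1] <= tol_da:
            tot = out_in[-1] + i
            out_mz[-1] = (out_mz[-1] * out_in[-1] + m * i) / tot
            out_in[-1] = tot
        else:
            out_mz.append(float(m))
            out_in.append(float(i))
    return np.array(out_mz), np.array(out_in)


@dataclass
class _MatrixCompound:
    mz: float
    rt: float
    apex: float
    fragments: List[Tuple[float, float]]  # (mz, relative intensity 0-1)


def _make_matrix(rng: np.random.Generator, cfg: SimulationConfig) -> List[_MatrixCompound]:
    out = []
    lo, hi = cfg.scan_range
    for _ in range(cfg.matrix_peak_count):
        mz = float(rng.uniform(lo + 30.0, hi - 50.0))
        rt = float(rng.uniform(0.0, cfg.gradient_length))
        apex = float(cfg.matrix_intensity_median * rng.lognormal(0.0, 1.0))
        n_frag = int(rng.integers(3, 7))
        frags = sorted(
            (float(rng.uniform(50.0, mz - 10.0)), float(rng.uniform(0.05, 1.0)))
            for _ in range(n_frag)
        )
        out.append(_MatrixCompound(mz, rt, apex, frags))
    return out


def _gauss(t: float, apex_rt: float, fwhm: float) -> float:
    sigma = fwhm / 2.3548200450309493
    return math.exp(-0.5 * ((t - apex_rt) / sigma) ** 2)


def simulate_run(
    spikes: Sequence[SpikeSpec],
    cfg: SimulationConfig = SimulationConfig(),
    sample_id: str = "simulated",
    inclusion_mzs: Optional[Sequence[float]] = None,
) -> AcquiredRun:
    """Generate one acquisition: MS1 full scans plus DDA MS2 scans.

    ``inclusion_mzs`` is the DDA inclusion list; it defaults to the spiked
    compounds' precursor m/z values.  Chemical background is added at every
    inclusion m/z so extracted-ion chromatograms carry realistic noise.
    """
    for sp in spikes:
        if sp.entry.rt is None:
            raise ValueError(f"spike {sp.entry.name!r} has no defined retention time")
    rng = np.random.default_rng(cfg.seed)
    matrix = _make_matrix(rng, cfg)

    polarities = sorted({sp.entry.polarity for sp in spikes}, reverse=True) or [POSITIVE]
    if inclusion_mzs is None:
        inclusion: Dict[str, List[float]] = {}
        for sp in spikes:
            inclusion.setdefault(sp.entry.polarity, []).append(sp.entry.precursor_mz)
        for pol in polarities:
            inclusion.setdefault(pol, [])
    else:
        inclusion = {pol: sorted(inclusion_mzs) for pol in polarities}
    inclusion = {pol: sorted(set(v)) for pol, v in inclusion.items()}

    lo_rng, hi_rng = cfg.scan_range
    scans: List[MassSpectrum] = []
    last_fragmented: Dict[Tuple[str, float], float] = {}
    n_cycles = int(math.floor(cfg.gradient_length / cfg.ms1_cycle))

    for k in range(n_cycles):
        t = k * cfg.ms1_cycle
        pol = polarities[k % len(polarities)]
        mz_parts: List[np.ndarray] = []
        in_parts: List[np.ndarray] = []
        spike_level: List[Tuple[SpikeSpec, float]] = []

        for sp in spikes:
            if sp.entry.polarity != pol or sp.apex_intensity <= 0:
                continue
            level = sp.apex_intensity * _gauss(t, sp.entry.rt, cfg.peak_width_fwhm)
            if level < _MIN_SIGNAL:
                continue
            spike_level.append((sp, level))
            pat = sp.entry.isotope_pattern.peaks
            pm = np.array([p[0] for p in pat])
            pr = np.array([p[1] for p in pat])
            sig = level * pr / 100.0
            sig = sig + rng.normal(0.0, cfg.noise_sigma, sig.shape)
            mz_parts.append(_jitter_mz(rng, pm, cfg.mz_jitter_ppm))
            in_parts.append(np.clip(sig, 0.0, None))

        for mc in matrix:
            level = mc.apex * _gauss(t, mc.rt, cfg.peak_width_fwhm)
            if level < _MIN_SIGNAL:
                continue
            sig = level + rng.normal(0.0, cfg.noise_sigma)
            if sig > 0:
                mz_parts.append(_jitter_mz(rng, np.array([mc.mz]), cfg.mz_jitter_ppm))
                in_parts.append(np.array([sig]))

        # chemical background at each monitored (inclusion) channel
        incl = inclusion[pol]
        if incl and (cfg.noise_sigma > 0 or cfg.baseline > 0):
            ch = np.abs(rng.normal(cfg.baseline, cfg.noise_sigma, len(incl)))
            keep = ch > 0
            if keep.any():
                mz_parts.append(_jitter_mz(rng, np.asarray(incl)[keep], cfg.mz_jitter_ppm))
                in_parts.append(ch[keep])

        if cfg.noise_peaks_per_scan and cfg.noise_sigma > 0:
            nmz = rng.uniform(lo_rng, hi_rng, cfg.noise_peaks_per_scan)
            nin = np.abs(rng.normal(cfg.baseline, cfg.noise_sigma, cfg.noise_peaks_per_scan))
            keep = nin > 0
            mz_parts.append(nmz[keep])
            in_parts.append(nin[keep])

        if mz_parts:
            mz_all = np.concatenate(mz_parts)
            in_all = np.concatenate(in_parts)
            ok = (in_all > 0) & (mz_all >= lo_rng) & (mz_all <= hi_rng)
            mz_all, in_all = _merge_sorted(mz_all[ok], in_all[ok])
        else:
            mz_all = np.empty(0)
            in_all = np.empty(0)
        scans.append(MassSpectrum(mz_all, in_all, 1, pol, t))

        # -- DDA selection: top-N inclusion ions, dynamic exclusion ------------
        candidates: List[Tuple[float, float]] = []  # (intensity, target mz)
        for target in incl:
            half = target * 5e-6
            i, j = np.searchsorted(mz_all, [target - half, target + half])
            inten = float(in_all[i:j].sum())
            if inten < cfg.dda_min_intensity:
                continue
            last = last_fragmented.get((pol, target))
            if last is not None and t < last + cfg.dynamic_exclusion_s:
                continue
            candidates.append((inten, target))
        candidates.sort(key=lambda c: (-c[0], c[1]))

        for rank, (prec_inten, target) in enumerate(candidates[: cfg.dda_top_n]):
            last_fragmented[(pol, target)] = t
            fmz: List[float] = []
            fin: List[float] = []
            half_iso = cfg.isolation_window_mz / 2.0
            for sp, level in spike_level:
                if abs(sp.entry.precursor_mz - target) > half_iso:
                    continue
                scale = level * cfg.ms2_yield
                for m, rel in zip(sp.entry.ms2.mz, sp.entry.ms2.intensity):
                    fmz.append(m)
                    fin.append(scale * rel / 100.0)
            for mc in matrix:
                if abs(mc.mz - target) > half_iso:
                    continue
                level = mc.apex * _gauss(t, mc.rt, cfg.peak_width_fwhm)
                if level < _MIN_SIGNAL:
                    continue
                for m, rel in mc.fragments:
                    fmz.append(m)
                    fin.append(level * cfg.ms2_yield * rel)
            if not fmz:
                continue
            fmz_a = _jitter_mz(rng, np.array(fmz), cfg.mz_jitter_ppm)
            fin_a = np.array(fin) * rng.lognormal(0.0, cfg.ms2_noise_sigma, len(fin))
            fmz_a, fin_a = _merge_sorted(fmz_a, fin_a)
            keep = fin_a >= cfg.ms2_min_intensity
            if not keep.any():
                continue
            scans.append(
                MassSpectrum(
                    fmz_a[keep],
                    fin_a[keep],
                    2,
                    pol,
                    t + (rank + 1) * _MS2_SCAN_OFFSET,
                    precursor_mz=float(target),
                    collision_energy=(17.5, 35.0, 52.5),
                )
            )

    truth = [
        {
            "compound": sp.entry.name,
            "concentration_ug_per_l": sp.concentration,
            "response_factor": sp.response_factor,
            "rt_s": sp.entry.rt,
            "precursor_mz": sp.entry.precursor_mz,
            "polarity": sp.entry.polarity,
        }
        for sp in spikes
    ]
    return AcquiredRun(
        sample_id=sample_id,
        scans=scans,
        scan_range=cfg.scan_range,
        metadata={"seed": cfg.seed, "truth": truth, "config": cfg.__dict__.copy()},
    )


def dilution_series(
    entries: "LibraryEntry | Sequence[LibraryEntry]",
    concentrations: Sequence[float],
    n_replicates: int = 6,
    cfg: SimulationConfig = SimulationConfig(),
    response_factors: Optional[Dict[str, float]] = None,
) -> List[AcquiredRun]:
    """Replicate runs over a concentration ladder.

    Seeds derive deterministically from ``(cfg.seed, level index, replicate)``
    so the whole series is reproducible run by run.  Returns the flat list of
    ``len(concentrations) x n_replicates`` runs; each run's metadata records
    its level and replicate index.
    """
    if not concentrations:
        raise ValueError("concentrations must be a non-empty ascending list")
    if list(concentrations) != sorted(concentrations):
        raise ValueError("concentrations must be sorted ascending")
    if isinstance(entries, LibraryEntry):
        entries = [entries]
    runs: List[AcquiredRun] = []
    for li, conc in enumerate(concentrations):
        for rep in range(n_replicates):
            seed = (cfg.seed * 1_000_003 + li * 10_007 + rep) % (2**31)
            sub = replace(cfg, seed=seed)
            spikes = [
                SpikeSpec(e, conc, (response_factors or {}).get(e.name, 1000.0))
                for e in entries
            ]
            run = simulate_run(
                spikes, sub, sample_id=f"level{li}_rep{rep}"
            )
            run.metadata.update({"level_index": li, "concentration": conc, "replicate": rep})
            runs.append(run)
    return runs
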