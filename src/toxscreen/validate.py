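"""Guideline validation statistics for the screening method.

Implements the standard bioanalytical validation quantities on peak-area
tables and identification outcomes:

* **matrix effect** (ME) — post-extraction-spiked matrix vs neat solution;
* **recovery** (RE) — pre- vs post-extraction-spiked matrix;
* **process efficiency** (PE) — pre-extraction-spiked matrix vs neat;
* **limit of identification** (LOI) — lowest concentration at which every
  replicate satisfies the three major identification criteria;
* **spectra reproducibility** — mean and RSD of the library score across
  replicate days.

Ratio statistics are computed replicate-pairwise (replicate *i* against
replicate *i*), not as a ratio of means: this matches the paired design of
the two sample sets and preserves the algebraic identity PE = ME x RE
exactly when all three quantities come from the same area tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .detect import build_xic, detect_peaks
from .ident import IdentificationSettings, identify
from .simulate import SimulationConfig, SpikeSpec, simulate_run
from .speclib import SpectralLibrary

__all__ = [
    "AreaSet",
    "RatioStat",
    "LOITable",
    "replicate_ratios",
    "matrix_effect",
    "recovery",
    "process_efficiency",
    "determine_loi",
    "spectra_reproducibility",
    "CampaignConfig",
    "ValidationSummary",
    "run_validation_campaign",
]

NEAT = "neat"
SPIKED_AFTER = "spiked_after_extraction"
SPIKED_BEFORE = "spiked_before_extraction"
_CONDITIONS = (NEAT, SPIKED_AFTER, SPIKED_BEFORE)


@dataclass
class AreaSet:
    """Replicate peak areas for one compound under one sample condition."""

    compound: str
    condition: str
    level: float  # ug/L
    areas: np.ndarray  # a.u. * s

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1 or self.areas.size < 2:
            raise ValueError("an AreaSet needs at least two replicate areas")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")

    @property
    def n(self) -> int:
        return int(self.areas.size)


@dataclass
class RatioStat:
    mean: float
    rsd: float  # percent
    n: int

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("ratio mean must be positive")
        if self.rsd < 0:
            raise ValueError("rsd must be non-negative")


def _pairwise_ratio(num: AreaSet, den: AreaSet) -> RatioStat:
    if num.compound != den.compound:
        raise ValueError(f"compound mismatch: {num.compound!r} vs {den.compound!r}")
    if num.level != den.level:
        raise ValueError(f"level mismatch: {num.level} vs {den.level}")
    if num.n != den.n:
        raise ValueError(f"replicate count mismatch: {num.n} vs {den.n}")
    r = num.areas / den.areas
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    return RatioStat(mean=mean, rsd=100.0 * sd / mean, n=num.n)


def replicate_ratios(num: AreaSet, den: AreaSet) -> np.ndarray:
    """Replicate-wise ratio vector (replicate i over replicate i)."""
    if num.compound != den.compound or num.level != den.level or num.n != den.n:
        raise ValueError("area sets must share compound, level and replicate count")
    return num.areas / den.areas


def matrix_effect(spiked_after: AreaSet, neat: AreaSet) -> RatioStat:
    """Ionisation suppression/enhancement: post-extraction spike over neat."""
    if spiked_after.condition != SPIKED_AFTER or neat.condition != NEAT:
        raise ValueError("matrix_effect expects (spiked_after_extraction, neat)")
    return _pairwise_ratio(spiked_after, neat)


def recovery(spiked_before: AreaSet, spiked_after: AreaSet) -> RatioStat:
    """Extraction yield: pre-extraction spike over post-extraction spike."""
    if spiked_before.condition != SPIKED_BEFORE or spiked_after.condition != SPIKED_AFTER:
        raise ValueError("recovery expects (spiked_before_extraction, spiked_after_extraction)")
    return _pairwise_ratio(spiked_before, spiked_after)


def process_efficiency(spiked_before: AreaSet, neat: AreaSet) -> RatioStat:
    """Overall yield: pre-extraction spike over neat; equals ME x RE."""
    if spiked_before.condition != SPIKED_BEFORE or neat.condition != NEAT:
        raise ValueError("process_efficiency expects (spiked_before_extraction, neat)")
    return _pairwise_ratio(spiked_before, neat)


@dataclass
class LOITable:
    """Per-level, per-replicate pass/fail matrix of the major criteria."""

    compound: str
    levels: Sequence[float]  # ug/L, ascending
    pass_matrix: np.ndarray  # shape (n_levels, n_replicates), bool

    def __post_init__(self) -> None:
        self.levels = [float(x) for x in self.levels]
        if not self.levels:
            raise ValueError("LOI table must contain at least one level")
        if self.levels != sorted(self.levels):
            raise ValueError("levels must be ascending")
        self.pass_matrix = np.asarray(self.pass_matrix, dtype=bool)
        if self.pass_matrix.ndim != 2 or self.pass_matrix.shape[0] != len(self.levels):
            raise ValueError("pass_matrix must be (n_levels, n_replicates)")


def determine_loi(t: LOITable, require_monotone: bool = True) -> Optional[float]:
    """Lowest concentration identified in *all* replicates.

    With ``require_monotone`` (default), every higher level must also be
    all-pass — a guard against non-monotone flukes.  Returns ``None`` when no
    level qualifies ("not reached").
    """
    all_pass = t.pass_matrix.all(axis=1)
    for i, ok in enumerate(all_pass):
        if ok and (not require_monotone or all_pass[i:].all()):
            return t.levels[i]
    return None


def spectra_reproducibility(scores: Sequence[float]) -> RatioStat:
    """Mean and relative standard deviation of replicate library scores."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2:
        raise ValueError("reproducibility needs at least two replicate scores")
    mean = float(arr.mean())
    if mean <= 0:
        raise ValueError("mean library score must be positive")
    sd = float(arr.std(ddof=1))
    return RatioStat(mean=mean, rsd=100.0 * sd / mean, n=int(arr.size))


# -- simulated validation campaign --------------------------------------------


@dataclass(frozen=True)
class CampaignConfig:
    """Design of a simulated validation campaign.

    ``matrix_factors`` model per-compound ionisation suppression or
    enhancement of the matrix (1.0 = none); ``recovery_factor`` models the
    extraction yield applied on top for pre-extraction spikes.
    """

    me_levels: Sequence[float] = (50.0, 500.0)
    loi_levels: Sequence[float] = (1.0, 5.0, 10.0, 50.0)
    n_replicates: int = 6
    base_response: float = 1000.0  # a.u. per ug/L in neat solution
    recovery_factor: float = 0.9
    matrix_factors: Dict[str, float] = field(default_factory=dict)
    compounds: Optional[Sequence[str]] = None  # default: whole library
    sim: SimulationConfig = SimulationConfig()
    settings: IdentificationSettings = IdentificationSettings()
    seed: int = 0


@dataclass
class ValidationSummary:
    ratios: pd.DataFrame  # compound, level, metric (ME/RE/PE), mean, rsd, n
    loi: pd.DataFrame  # compound, loi_ug_per_l (NaN = not reached)
    reproducibility: pd.DataFrame  # compound, level, mean_score, rsd, n

    def to_json(self, path: str) -> str:
        import json

        doc = {
            "ratios": self.ratios.to_dict(orient="records"),
            "loi": self.loi.to_dict(orient="records"),
            "reproducibility": self.reproducibility.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, default=float)
        return str(path)

    def to_tsv(self, prefix: str) -> List[str]:
        paths = []
        for name, df in (
            ("ratios", self.ratios),
            ("loi", self.loi),
            ("reproducibility", self.reproducibility),
        ):
            p = f"{prefix}_{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        return paths


def _peak_area(run, entry, settings: IdentificationSettings) -> float:
    """Area of the precursor XIC peak nearest the library RT.

    Falls back to integrating the XIC over the expected elution window when
    peak detection finds nothing (keeps area tables complete at low signal).
    """
    xic = build_xic(run, entry.precursor_mz, settings.precursor_tol_ppm, entry.polarity)
    peaks = detect_peaks(xic, snr_min=settings.snr_min)
    rt = entry.rt if entry.rt is not None else float(xic.rt[np.argmax(xic.intensity)])
    near = [p for p in peaks if abs(p.rt_apex - rt) <= 15.0]
    if near:
        return max(near, key=lambda p: p.height).area
    sel = (xic.rt >= rt - 15.0) & (xic.rt <= rt + 15.0)
    area = float(np.trapezoid(xic.intensity[sel], xic.rt[sel])) if sel.sum() >= 2 else 0.0
    return max(area, 1e-6)


def _condition_response(cfg: CampaignConfig, condition: str, name: str) -> float:
    mf = cfg.matrix_factors.get(name, 1.0)
    if condition == NEAT:
        return cfg.base_response
    if condition == SPIKED_AFTER:
        return cfg.base_response * mf
    return cfg.base_response * mf * cfg.recovery_factor


def run_validation_campaign(lib: SpectralLibrary, cfg: CampaignConfig) -> ValidationSummary:
    """Simulate and evaluate a full validation campaign over a compound panel."""
    names = list(cfg.compounds) if cfg.compounds else [e.name for e in lib.entries]
    panel = SpectralLibrary([lib[n] for n in names])

    # --- ME / RE / PE from paired replicate area sets ------------------------
    ratio_rows = []
    area_sets: Dict[tuple, AreaSet] = {}
    for li, level in enumerate(cfg.me_levels):
        for ci, condition in enumerate(_CONDITIONS):
            areas = {n: [] for n in names}
            for rep in range(cfg.n_replicates):
                seed = (cfg.seed * 7_654_321 + li * 911 + ci * 97 + rep) % (2**31)
                sim = replace(cfg.sim, seed=seed)
                spikes = [
                    SpikeSpec(panel[n], level, _condition_response(cfg, condition, n))
                    for n in names
                ]
                run = simulate_run(spikes, sim, sample_id=f"{condition}_L{li}_r{rep}")
                for n in names:
                    areas[n].append(_peak_area(run, panel[n], cfg.settings))
            for n in names:
                area_sets[(n, condition, level)] = AreaSet(
                    n, condition, level, np.array(areas[n])
                )
        for n in names:
            me = matrix_effect(area_sets[(n, SPIKED_AFTER, level)], area_sets[(n, NEAT, level)])
            re_ = recovery(
                area_sets[(n, SPIKED_BEFORE, level)], area_sets[(n, SPIKED_AFTER, level)]
            )
            pe = process_efficiency(
                area_sets[(n, SPIKED_BEFORE, level)], area_sets[(n, NEAT, level)]
            )
            for metric, stat in (("ME", me), ("RE", re_), ("PE", pe)):
                ratio_rows.append(
                    {
                        "compound": n,
                        "level_ug_per_l": level,
                        "metric": metric,
                        "mean": stat.mean,
                        "rsd_percent": stat.rsd,
                        "n": stat.n,
                    }
                )

    # --- LOI from replicate identification at each ladder level --------------
    loi_levels = [float(x) for x in cfg.loi_levels]
    pass_mats = {n: np.zeros((len(loi_levels), cfg.n_replicates), dtype=bool) for n in names}
    scores: Dict[str, List[float]] = {n: [] for n in names}
    for li, level in enumerate(loi_levels):
        for rep in range(cfg.n_replicates):
            seed = (cfg.seed * 33_554_467 + li * 1_213 + rep) % (2**31)
            sim = replace(cfg.sim, seed=seed)
            spikes = [
                SpikeSpec(panel[n], level, _condition_response(cfg, SPIKED_BEFORE, n))
                for n in names
            ]
            run = simulate_run(spikes, sim, sample_id=f"loi_L{li}_r{rep}")
            for res in identify(run, panel, cfg.settings):
                pass_mats[res.entry.name][li, rep] = res.identified
                if li == len(loi_levels) - 1 and res.si is not None:
                    scores[res.entry.name].append(float(res.si))

    loi_rows = []
    for n in names:
        loi = determine_loi(LOITable(n, loi_levels, pass_mats[n]))
        loi_rows.append({"compound": n, "loi_ug_per_l": np.nan if loi is None else loi})

    repro_rows = []
    for n in names:
        if len(scores[n]) >= 2:
            stat = spectra_reproducibility(scores[n])
            repro_rows.append(
                {
                    "compound": n,
                    "level_ug_per_l": loi_levels[-1],
                    "mean_score": stat.mean,
                    "rsd_percent": stat.rsd,
                    "n": stat.n,
                }
            )
        else:
            repro_rows.append(
                {
                    "compound": n,
                    "level_ug_per_l": loi_levels[-1],
                    "mean_score": np.nan,
                    "rsd_percent": np.nan,
                    "n": len(scores[n]),
                }
            )

    return ValidationSummary(
        ratios=pd.DataFrame(ratio_rows),
        loi=pd.DataFrame(loi_rows),
        reproducibility=pd.DataFrame(repro_rows),
    )


def read_area_csv(path: str) -> List[AreaSet]:
    """Load replicate areas from a CSV with columns
    compound, condition, level, replicate, area."""
    df = pd.read_csv(path)
    required = {"compound", "condition", "level", "replicate", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (comp, cond, level), g in df.groupby(["compound", "condition", "level"]):
        g = g.sort_values("replicate")
        out.append(AreaSet(str(comp), str(cond), float(level), g["area"].to_numpy()))
    return out
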