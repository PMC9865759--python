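"""Criterion evaluation, match factors, and the major/minor decision rule."""

import numpy as np
import pytest

from toxscreen.ident import (
    IdentificationSettings,
    identify,
    isotope_fit,
    match_fragments,
    match_precursor,
    match_rt,
    spectral_scores,
)
from toxscreen.simulate import SimulationConfig, SpikeSpec, simulate_run
from toxscreen.speclib import ISOMER_PAIRS, SpectralLibrary
from toxscreen.spectra_io import MassSpectrum


def _ms2(mz, inten, precursor):
    order = np.argsort(mz)
    return MassSpectrum(
        np.asarray(mz, float)[order],
        np.asarray(inten, float)[order],
        2,
        "+",
        10.0,
        precursor_mz=precursor,
    )


def _spiked_run(lib, name, conc=200.0, seed=77):
    cfg = SimulationConfig(gradient_length=420.0, seed=seed)
    return simulate_run(
        [SpikeSpec(lib[name], conc)],
        cfg,
        sample_id=f"spike_{name}",
        inclusion_mzs=[e.precursor_mz for e in lib.entries],
    )


class TestSettings:
    def test_defaults_are_published_operating_point(self, settings):
        assert settings.precursor_tol_ppm == 5.0
        assert settings.fragment_tol_mmu == 10.0
        assert settings.min_fragments == 1
        assert settings.fragment_intensity_min == 5000.0
        assert settings.rt_window_s == 60.0
        assert settings.isotope_fit_min == 70.0
        assert settings.si_min == 500.0
        assert settings.rsi_min == 600.0
        assert settings.library_score_min == 20.0
        assert settings.snr_min == 10.0

    def test_nonpositive_tolerances_rejected(self):
        with pytest.raises(ValueError):
            IdentificationSettings(precursor_tol_ppm=0.0)
        with pytest.raises(ValueError):
            IdentificationSettings(rt_window_s=-1.0)


class TestMatchPrecursor:
    def test_simulated_spike_passes_with_small_ppm_error(self, fixture_lib, settings):
        run = _spiked_run(fixture_lib, "Tramadol")
        res = match_precursor(run, fixture_lib["Tramadol"], settings)
        assert res.passed
        assert abs(res.value) <= 5.0  # ppm

    def test_blank_run_fails(self, fixture_lib, settings):
        cfg = SimulationConfig(gradient_length=420.0, seed=5)
        blank = simulate_run(
            [], cfg, inclusion_mzs=[e.precursor_mz for e in fixture_lib.entries]
        )
        assert not match_precursor(blank, fixture_lib["Tramadol"], settings).passed

    def test_different_nominal_mass_not_confused(self, fixture_lib, settings):
        """Amitriptyline-like vs venlafaxine-like windows (75 ppm apart) don't overlap."""
        from toxscreen.speclib import make_entry

        ami = make_entry("Amitriptyline", "C20H23N", "+", 6.38, 278.19033,
                         [(233.13248, 100.0)])
        ven = make_entry("Venlafaxine", "C17H27NO2", "+", 5.14, 278.21146,
                         [(58.06595, 100.0)])
        lib = SpectralLibrary([ami, ven])
        run = _spiked_run(lib, "Amitriptyline", seed=13)
        assert match_precursor(run, ami, IdentificationSettings()).passed
        assert not match_precursor(run, ven, IdentificationSettings()).passed


class TestMatchFragments:
    def test_within_10mmu_and_intense_enough(self, fixture_lib, settings):
        e = fixture_lib["Tramadol"]
        obs = _ms2([58.0660], [6000.0], e.precursor_mz)
        res = match_fragments(obs, e, settings)
        assert res.passed
        assert res.detail["matched"][0]["delta_mmu"] == pytest.approx(0.05, abs=0.01)

    def test_just_outside_tolerance_not_matched(self, fixture_lib, settings):
        e = fixture_lib["Tramadol"]
        obs = _ms2([58.0760], [6000.0], e.precursor_mz)  # 10.05 mmu away
        assert not match_fragments(obs, e, settings).passed

    def test_below_intensity_threshold_fails(self, fixture_lib, settings):
        e = fixture_lib["Tramadol"]
        obs = _ms2([58.06595, 246.1843], [4999.0, 4999.0], e.precursor_mz)
        assert not match_fragments(obs, e, settings).passed

    def test_precursor_survivor_does_not_count_as_fragment(self, fixture_lib, settings):
        e = fixture_lib["Tramadol"]
        obs = _ms2([e.precursor_mz], [1e6], e.precursor_mz)
        assert not match_fragments(obs, e, settings).passed


class TestSpectralScores:
    def test_self_match_is_999(self, fixture_lib, settings):
        for e in fixture_lib:
            si, rsi = spectral_scores(e.ms2, e, settings)
            assert si == 999 and rsi == 999

    def test_disjoint_spectra_score_zero(self, fixture_lib, settings):
        e = fixture_lib["Tramadol"]
        obs = _ms2([400.1, 450.2, 500.3], [100.0, 50.0, 10.0], e.precursor_mz)
        assert spectral_scores(obs, e, settings) == (0, 0)

    def test_noise_superset_keeps_rsi_at_999(self, fixture_lib, settings):
        e = fixture_lib["MDEA"]
        mz = np.concatenate([e.ms2.mz, [401.3, 455.7, 512.9, 577.2, 603.4]])
        inten = np.concatenate([e.ms2.intensity, [8.0, 6.0, 5.0, 4.0, 3.0]])
        obs = _ms2(mz, inten, e.precursor_mz)
        si, rsi = spectral_scores(obs, e, settings)
        assert rsi == 999
        assert si < 999
        assert rsi >= si

    def test_cross_isomer_scores_fail_thresholds(self, fixture_lib, settings):
        """Reference spectra of isomer partners never satisfy SI>=500 & RSI>=600."""
        for a, b in ISOMER_PAIRS:
            for query, lib_entry in ((a, b), (b, a)):
                si, rsi = spectral_scores(
                    fixture_lib[query].ms2, fixture_lib[lib_entry], settings
                )
                assert si < settings.si_min or rsi < settings.rsi_min, (query, lib_entry)

    def test_empty_spectrum_is_error(self, fixture_lib, settings):
        e = fixture_lib["Tramadol"]
        empty = MassSpectrum(np.array([]), np.array([]), 2, "+", 1.0, precursor_mz=e.precursor_mz)
        with pytest.raises(ValueError):
            spectral_scores(empty, e, settings)


class TestMatchRt:
    def test_undefined_library_rt_always_passes(self, settings):
        from toxscreen.speclib import make_entry

        e = make_entry("NoRT", "C16H25NO2", "+", None, None, [(58.066, 100.0)])
        assert match_rt(1234.5, e, settings).passed
        assert match_rt(None, e, settings).passed

    def test_exact_rt_passes(self, fixture_lib, settings):
        e = fixture_lib["Tramadol"]
        assert match_rt(4.42 * 60.0, e, settings).passed

    def test_morphine_vs_tramadol_rt_fails(self, fixture_lib, settings):
        # 4.42 min observed against the 1.27 min morphine entry: 189 s > 60 s
        res = match_rt(4.42 * 60.0, fixture_lib["Morphine"], settings)
        assert not res.passed
        assert res.value == pytest.approx(189.0, abs=0.1)


class TestIsotopeFit:
    def _ms1_from_pattern(self, entry, scale=1e5, distort=None):
        peaks = [(m, r * scale / 100.0) for m, r in entry.isotope_pattern.peaks]
        if distort:
            peaks = [(m, i * distort.get(round(m - peaks[0][0]), 1.0)) for m, i in peaks]
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        return MassSpectrum(mz, inten, 1, "+", 100.0)

    def test_perfect_pattern_scores_100(self, fixture_lib, settings):
        e = fixture_lib["Oxazepam"]
        res = isotope_fit(self._ms1_from_pattern(e), e, settings)
        assert res.passed
        assert res.value == pytest.approx(100.0, abs=1e-6)

    def test_all_unmatched_scores_zero(self, fixture_lib, settings):
        e = fixture_lib["Oxazepam"]
        ms1 = MassSpectrum(np.array([500.0]), np.array([1e5]), 1, "+", 100.0)
        res = isotope_fit(ms1, e, settings)
        assert not res.passed
        assert res.value == 0.0

    def test_halved_m_plus_2_scored_by_mean_deviation(self, fixture_lib, settings):
        """Chlorinated compound with M+2 at half its predicted intensity."""
        e = fixture_lib["Oxazepam"]
        ms1 = self._ms1_from_pattern(e, distort={2: 0.5})
        res = isotope_fit(ms1, e, settings)
        predicted = [(m, r) for m, r in e.isotope_pattern.peaks if r >= 5.0]
        devs = []
        for m, r in predicted:
            shift = round(m - predicted[0][0])
            obs = r * (0.5 if shift == 2 else 1.0)
            devs.append(min(abs(obs - r), 30.0))
        expected = 100.0 * (1.0 - np.mean(devs) / 30.0)
        assert res.value == pytest.approx(expected, abs=1e-6)
        assert res.passed == (expected >= 70.0)


class TestIdentify:
    def test_spiked_compound_identified_isomer_rejected(self, fixture_lib):
        run = _spiked_run(fixture_lib, "Tramadol")
        results = {r.entry.name: r for r in identify(run, fixture_lib)}
        assert results["Tramadol"].identified
        assert not results["O-Demethylvenlafaxine"].identified
        # the co-isomer still shows a precursor peak (same exact mass) ...
        assert results["O-Demethylvenlafaxine"].criteria["precursor"].passed
        # ... but fails the spectrum-match major criterion
        assert not results["O-Demethylvenlafaxine"].criteria["library_match"].passed

    def test_minor_criteria_never_veto(self, fixture_lib):
        """An RT mismatch alone must not block identification."""
        import dataclasses

        run = _spiked_run(fixture_lib, "Tramadol")
        entries = []
        for e in fixture_lib:
            if e.name == "Tramadol":
                e = dataclasses.replace(e, rt=60.0)  # wrong by ~3.4 min
            entries.append(e)
        shifted = SpectralLibrary(entries)
        res = {r.entry.name: r for r in identify(run, shifted)}["Tramadol"]
        assert not res.criteria["rt"].passed
        assert res.identified  # major criteria only

    def test_blank_identifies_nothing(self, fixture_lib):
        cfg = SimulationConfig(gradient_length=420.0, seed=99)
        blank = simulate_run(
            [], cfg, inclusion_mzs=[e.precursor_mz for e in fixture_lib.entries]
        )
        assert sum(r.identified for r in identify(blank, fixture_lib)) == 0

    def test_invariant_to_library_order(self, fixture_lib):
        run = _spiked_run(fixture_lib, "Naloxone", seed=31)
        fwd = identify(run, fixture_lib)
        rev = identify(run, SpectralLibrary(list(reversed(fixture_lib.entries))))
        by_name_fwd = {r.entry.name: (r.identified, r.si, r.rsi) for r in fwd}
        by_name_rev = {r.entry.name: (r.identified, r.si, r.rsi) for r in rev}
        assert by_name_fwd == by_name_rev

    def test_monotone_in_concentration(self, fixture_lib):
        """Raising the spiked concentration never loses the identification."""
        identified = []
        for conc in (20.0, 50.0, 100.0, 200.0, 500.0):
            run = _spiked_run(fixture_lib, "MDEA", conc=conc, seed=55)
            res = {r.entry.name: r for r in identify(run, fixture_lib)}
            identified.append(res["MDEA"].identified)
        first_hit = identified.index(True) if True in identified else len(identified)
        assert all(identified[first_hit:]), identified

    def test_empty_library_is_error(self, fixture_lib):
        run = _spiked_run(fixture_lib, "Tramadol", seed=2)
        with pytest.raises(ValueError):
            identify(run, SpectralLibrary([]))

    def test_results_sorted_identified_first_then_si(self, fixture_lib):
        run = _spiked_run(fixture_lib, "Oxazepam", seed=41)
        results = identify(run, fixture_lib)
        flags = [r.identified for r in results]
        assert flags == sorted(flags, reverse=True)
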