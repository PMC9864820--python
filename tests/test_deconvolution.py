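"""Deconvolution: window detection, averaging, charge assignment, top-N."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from venomics import (
    PROTON_MASS,
    Chromatogram,
    DeconvParams,
    ElutionWindow,
    Peak,
    PlantedToxin,
    Run,
    SampleMetadata,
    SimulationConfig,
    Spectrum,
    average_spectrum,
    deconvolve,
    detect_elution_windows,
    extract_eic,
    synthesize_run,
    top_abundant_toxins,
    total_ion_chromatogram,
)
from venomics.simulate import charge_states_for_mass

from conftest import make_truth


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    mass=st.floats(1000.0, 30000.0, allow_nan=False),
    z=st.integers(1, 30),
)
def test_mz_mass_round_trip(mass, z):
    mz = (mass + z * PROTON_MASS) / z
    assert z * (mz - PROTON_MASS) == pytest.approx(mass, rel=1e-9)


class TestElutionWindows:
    @staticmethod
    def gaussian_tic(centers, amps, n=200, dt=0.1, sigma=0.3):
        rt = np.arange(n) * dt
        inten = np.zeros(n)
        for c, a in zip(centers, amps):
            inten += a * np.exp(-((rt - c) ** 2) / (2 * sigma**2))
        return Chromatogram(rt, inten)

    def test_flat_tic_yields_no_window(self):
        tic = Chromatogram(np.arange(50) * 0.1, np.full(50, 10.0))
        assert detect_elution_windows(tic, min_snr=1.5) == []

    def test_all_zero_tic_yields_no_window(self):
        tic = Chromatogram(np.arange(50) * 0.1, np.zeros(50))
        assert detect_elution_windows(tic) == []

    def test_single_gaussian_yields_one_window_containing_apex(self):
        tic = self.gaussian_tic([10.0], [1000.0])
        windows = detect_elution_windows(tic, min_snr=1.5)
        assert len(windows) == 1
        assert windows[0].rt_start <= 10.0 <= windows[0].rt_end
        assert windows[0].apex_rt == pytest.approx(10.0, abs=0.1)

    def test_two_separated_gaussians_yield_two_disjoint_windows(self):
        tic = self.gaussian_tic([6.0, 14.0], [1000.0, 800.0])
        windows = detect_elution_windows(tic, min_snr=1.5)
        assert len(windows) == 2
        assert windows[0].rt_end < windows[1].rt_start


class TestAverageSpectrum:
    def run_of(self, spectra):
        return Run(metadata=SampleMetadata("S1"), spectra=spectra, mz_min=500, mz_max=5500)

    def test_weighted_merge_worked_example(self):
        run = self.run_of(
            [
                Spectrum(1.0, [1000.00], [10.0]),
                Spectrum(1.1, [1000.01], [20.0]),
            ]
        )
        peaks = average_spectrum(run, ElutionWindow(0.9, 1.2, 1.0), mz_merge_tol=0.05)
        assert len(peaks) == 1
        assert peaks[0].mz == pytest.approx((10 * 1000.00 + 20 * 1000.01) / 30, abs=1e-6)
        assert peaks[0].intensity == pytest.approx(15.0)

    def test_single_spectrum_is_identity(self):
        run = self.run_of([Spectrum(1.0, [1000.0, 1234.5], [5.0, 6.0])])
        peaks = average_spectrum(run, ElutionWindow(0.5, 1.5, 1.0))
        assert [(p.mz, p.intensity) for p in peaks] == [(1000.0, 5.0), (1234.5, 6.0)]

    def test_peaks_beyond_tolerance_stay_distinct(self):
        run = self.run_of([Spectrum(1.0, [1000.0, 1000.2], [5.0, 6.0])])
        peaks = average_spectrum(run, ElutionWindow(0.5, 1.5, 1.0), mz_merge_tol=0.05)
        assert len(peaks) == 2

    def test_empty_window_returns_nothing(self):
        run = self.run_of([Spectrum(1.0, [1000.0], [5.0])])
        assert average_spectrum(run, ElutionWindow(5.0, 6.0, 5.5)) == []


def brute_force_best_envelope(peaks, z_min, z_max, tol, min_charges, cutoff):
    """Independent oracle: enumerate every mass window over all (peak, z) pairs.

    Members are the per-charge highest-intensity candidates (a peak cannot
    support two charges inside one window for mz > m_p + tol, so per-charge
    dedup is sufficient). Returns the best (n_charges, intensity, -mass) key
    and its member set.
    """
    cands = []
    for pi, p in enumerate(peaks):
        for z in range(z_min, z_max + 1):
            mass = z * (p.mz - PROTON_MASS)
            if mass > 0:
                cands.append((mass, z, pi, p.intensity))
    cands.sort()
    best = None
    for i in range(len(cands)):
        window = [c for c in cands if cands[i][0] <= c[0] <= cands[i][0] + tol]
        by_charge = {}
        for mass, z, pi, inten in window:
            cur = by_charge.get(z)
            if cur is None or inten > cur[3] or (inten == cur[3] and mass < cur[0]):
                by_charge[z] = (mass, z, pi, inten)
        total = math.fsum(c[3] for c in by_charge.values())
        est = (
            math.fsum(c[0] * c[3] for c in by_charge.values()) / total
            if total > 0
            else np.mean([c[0] for c in by_charge.values()])
        )
        if est > cutoff and len(by_charge) < min_charges:
            continue
        key = (-len(by_charge), -total, est)
        if best is None or key < best[0]:
            best = (key, {(c[1], c[2]) for c in by_charge.values()})
    return best


class TestDeconvolve:
    def test_triple_charge_envelope_worked_example(self):
        peaks = [Peak(1481.8962, 100.0), Peak(1333.8073, 100.0), Peak(1212.6436, 100.0)]
        envelopes = deconvolve(peaks, z_min=1, z_max=30, mass_cluster_tol=0.05)
        assert envelopes
        top = envelopes[0]
        assert top.neutral_mass == pytest.approx(13328.0, abs=0.02)
        assert top.charges == (9, 10, 11)

    def test_single_peak_single_charge(self):
        envelopes = deconvolve([Peak(1001.007276, 10.0)], z_min=1, z_max=1)
        assert envelopes[0].neutral_mass == pytest.approx(1000.0, abs=1e-6)

    def test_adjacent_charge_closed_form(self):
        # charge of the lower-m/z peak from two adjacent charge states
        mz_hi, mz_lo = 1481.8962, 1333.8073
        z = (mz_hi - PROTON_MASS) / (mz_hi - mz_lo)
        assert z == pytest.approx(10.0, abs=1e-3)

    def test_empty_peak_list(self):
        assert deconvolve([]) == []

    def test_harmonic_ambiguity_resolved_to_lower_mass(self):
        # the same peaks support 2M at doubled charges with equal intensity;
        # the mass tie-break must emit M
        peaks = [Peak((13328.0 + z * PROTON_MASS) / z, 50.0) for z in (9, 10, 11)]
        top = deconvolve(peaks, z_max=30)[0]
        assert top.neutral_mass == pytest.approx(13328.0, abs=0.02)

    def test_greedy_top_envelope_matches_exhaustive_oracle(self, rng):
        params = dict(z_min=1, z_max=20, mass_cluster_tol=0.1, min_charges=2)
        for _ in range(60):
            peaks = _random_spectrum(rng, max_peaks=30)
            if not peaks:
                continue
            oracle = brute_force_best_envelope(
                peaks, 1, 20, 0.1, 2, cutoff=5000.0
            )
            got = deconvolve(peaks, small_mass_cutoff=5000.0, **params)
            if oracle is None:
                assert got == []
            else:
                top = got[0]
                members = {(z, _peak_index(peaks, mz)) for z, mz, _i in top.members}
                assert members == oracle[1]


def _peak_index(peaks, mz):
    return int(np.argmin([abs(p.mz - mz) for p in peaks]))


def _random_spectrum(rng, max_peaks=30):
    """Realistic random spectrum: 1–3 planted envelopes plus stray peaks."""
    peaks = []
    for _ in range(rng.integers(1, 4)):
        mass = float(rng.uniform(2000, 20000))
        z_apex = max(1, round(mass / 1200))
        for z in range(max(1, z_apex - 2), z_apex + 3):
            mz = (mass + z * PROTON_MASS) / z
            if 500 <= mz <= 5500:
                peaks.append(Peak(mz, float(rng.uniform(10, 1000))))
    n_noise = int(rng.integers(0, 8))
    for _ in range(n_noise):
        peaks.append(Peak(float(rng.uniform(500, 5500)), float(rng.uniform(1, 100))))
    peaks = sorted(peaks, key=lambda p: p.mz)[:max_peaks]
    return peaks


class TestEic:
    def test_empty_window_gives_zero_series(self):
        run = Run(
            metadata=SampleMetadata("S1"),
            spectra=[Spectrum(0.5, [1000.0], [5.0]), Spectrum(1.0, [1001.0], [3.0])],
        )
        eic = extract_eic(run, 2000.0, 0.05)
        assert np.array_equal(eic.intensity, [0.0, 0.0])

    def test_widening_tolerance_never_decreases(self, single_toxin_run):
        run, toxin = single_toxin_run
        mz = (toxin.neutral_mass + 10 * PROTON_MASS) / 10
        narrow = extract_eic(run, mz, 0.02).intensity
        wide = extract_eic(run, mz, 0.2).intensity
        assert np.all(wide >= narrow - 1e-12)

    def test_apex_matches_planted_rt(self, single_toxin_run, clean_config):
        run, toxin = single_toxin_run
        mz = (toxin.neutral_mass + 11 * PROTON_MASS) / 11
        eic = extract_eic(run, mz, 0.05)
        apex_rt = eic.rt[np.argmax(eic.intensity)]
        assert abs(apex_rt - toxin.rt_center) <= 1.0 / (clean_config.scan_hz * 60.0)


class TestTopAbundantToxins:
    def test_recovers_the_most_intense_planted_toxins(self, clean_config, rng):
        # 20 toxins spanning 100-fold intensity with a clear gap below rank 12
        masses = np.sort(rng.uniform(5200, 14800, 20))
        masses = masses[(masses < 9000) | (masses > 13000)]
        while len(masses) < 20:
            masses = np.append(masses, rng.uniform(5200, 8900))
        rts = rng.uniform(3.0, 16.0, 20)
        amps = np.concatenate([rng.uniform(1e4, 1e5, 12), rng.uniform(1e3, 2.5e3, 8)])
        toxins = [
            PlantedToxin(
                f"T{i:02d}",
                float(masses[i]),
                float(rts[i]),
                float(amps[i]),
                charge_states_for_mass(float(masses[i]), 500, 5500),
                {"S1": 1.0},
            )
            for i in range(20)
        ]
        truth = make_truth(toxins, config=clean_config)
        run = synthesize_run(truth, "S1", clean_config)
        found = top_abundant_toxins(run, n_top=12)
        assert len(found) == 12
        top12_true = {t.toxin_id for t in sorted(toxins, key=lambda t: -t.base_intensity)[:12]}
        matched = set()
        for rec in found:
            deltas = [abs(rec.neutral_mass - t.neutral_mass) for t in toxins]
            j = int(np.argmin(deltas))
            assert deltas[j] <= 0.5
            matched.add(toxins[j].toxin_id)
        assert matched == top12_true

    def test_noise_free_masses_recovered_exactly(self, clean_config):
        toxins = [
            PlantedToxin(
                f"T{i}", m, rt, 1e4, charge_states_for_mass(m, 500, 5500), {"S1": 1.0}
            )
            for i, (m, rt) in enumerate([(6783.0, 5.0), (13328.0, 10.0), (14007.0, 15.0)])
        ]
        truth = make_truth(toxins, config=clean_config)
        run = synthesize_run(truth, "S1", clean_config)
        found = top_abundant_toxins(run, n_top=10)
        assert len(found) == 3
        for t in toxins:
            assert min(abs(f.neutral_mass - t.neutral_mass) for f in found) <= 0.01

    def test_noise_only_run_yields_nothing(self):
        cfg = SimulationConfig(seed=9, gradient_minutes=10.0)
        truth = make_truth([], config=cfg)
        run = synthesize_run(truth, "S1", cfg)
        assert top_abundant_toxins(run, n_top=12) == []

    def test_n_top_larger_than_toxin_count_returns_all(self, single_toxin_run):
        run, _ = single_toxin_run
        assert len(top_abundant_toxins(run, n_top=40)) == 1
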