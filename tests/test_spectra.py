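"""Spectrum processing: background, parent ion, envelope, decay fit."""

import numpy as np
import pytest

from chcid import (
    PeakSpectrum,
    SimSpectrumParams,
    detect_enhanced,
    determine_parent,
    extract_envelope,
    fit_decay,
    make_structure,
    simulate_spectrum,
    subtract_background,
)
from chcid.errors import DecayFitError, InsufficientEnvelopeError, NoParentError
from chcid.spectra import alkyl_series


@pytest.fixture(scope="module")
def hexacosane_clean():
    return simulate_spectrum(make_structure(26), SimSpectrumParams(noise_sd=0.0))


@pytest.fixture(scope="module")
def methylnonacosane_clean():
    return simulate_spectrum(make_structure(29, [9]),
                             SimSpectrumParams(noise_sd=0.0))


class TestSubtractBackground:
    def test_self_subtraction_zeroes(self, hexacosane_clean):
        out = subtract_background(hexacosane_clean, hexacosane_clean)
        assert np.all(out.intensities == 0.0)

    def test_empty_background_identity(self, hexacosane_clean):
        out = subtract_background(hexacosane_clean, None)
        assert out is hexacosane_clean

    def test_flat_background_reduces_by_constant(self, hexacosane_clean):
        c = 500.0
        bg = PeakSpectrum("bg", 0.0, hexacosane_clean.mz,
                          np.full(len(hexacosane_clean), c))
        out = subtract_background(hexacosane_clean, bg)
        expected = np.maximum(0.0, hexacosane_clean.intensities - c)
        assert np.allclose(out.intensities, expected)

    def test_empty_signal_rejected(self):
        empty = PeakSpectrum("e", 0.0, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            subtract_background(empty, None)


class TestDetermineParent:
    def test_alkane_series(self, methylnonacosane_clean):
        parent = determine_parent(methylnonacosane_clean)
        assert (parent.parent_mz, parent.molecular_formula,
                parent.carbon_count, parent.unsaturation) == (422, "C30H62", 30, 0)

    def test_alkene_series(self):
        spec = PeakSpectrum.from_pairs("p", 0.0,
                                       [(57, 1e5), (71, 8e4), (322, 5e3)])
        parent = determine_parent(spec)
        assert parent.molecular_formula == "C23H46"
        assert parent.carbon_count == 23 and parent.unsaturation == 1

    def test_off_series_top_ion_ambiguous(self):
        spec = PeakSpectrum.from_pairs("p", 0.0, [(423, 1e5)])
        parent = determine_parent(spec)
        assert parent.ambiguous and parent.molecular_formula is None

    def test_weak_molecular_ion_found_below_floor(self):
        # molecular ion at 0.1% of base: below the 0.5% floor, still assigned
        spec = PeakSpectrum.from_pairs("p", 0.0,
                                       [(57, 1e6), (71, 8e5), (366, 1e3)])
        parent = determine_parent(spec)
        assert parent.parent_mz == 366 and parent.ambiguous

    def test_no_parent_error(self):
        spec = PeakSpectrum.from_pairs("p", 0.0, [(57.0, 0.0)])
        with pytest.raises(NoParentError):
            determine_parent(spec)


class TestExtractEnvelope:
    def test_series_count_hexacosane(self, hexacosane_clean):
        parent = determine_parent(hexacosane_clean)
        env = extract_envelope(hexacosane_clean, parent)
        # m/z == 1 mod 14 between 57 and 366-15 inclusive
        assert len(env) == 22
        assert env[0][0] == 57 and env[-1][0] == 351

    def test_non_series_ions_excluded(self, hexacosane_clean):
        parent = determine_parent(hexacosane_clean)
        mz = np.sort(np.concatenate([hexacosane_clean.mz, [100.0, 200.0]]))
        inten = np.interp(mz, hexacosane_clean.mz, hexacosane_clean.intensities)
        spiked = PeakSpectrum("s", 0.0, mz, inten)
        env = extract_envelope(spiked, parent)
        assert all(m % 14 == 1 for m, _ in env)

    def test_upper_bound_m_minus_15(self):
        assert alkyl_series(226)[-1] == 211

    def test_insufficient_envelope(self):
        spec = PeakSpectrum.from_pairs("p", 0.0, [(57, 1.0), (71, 1.0), (226, 1.0)])
        parent = determine_parent(spec)
        with pytest.raises(InsufficientEnvelopeError):
            extract_envelope(spec, parent)


class TestFitDecay:
    def test_exact_recovery_on_clean_envelope(self, hexacosane_clean):
        parent = determine_parent(hexacosane_clean)
        fit = fit_decay(extract_envelope(hexacosane_clean, parent))
        assert fit.amplitude == pytest.approx(1e6, rel=1e-6)
        assert fit.decay_constant == pytest.approx(0.012, rel=1e-6)

    def test_constant_envelope_gives_zero_decay(self):
        env = [(57 + 14 * i, 5000.0) for i in range(8)]
        fit = fit_decay(env)
        assert fit.decay_constant == pytest.approx(0.0, abs=1e-12)

    def test_enhanced_ion_masked_on_refit(self):
        a, lam = 1e6, 0.012
        env = [(m, a * np.exp(-lam * m)) for m in range(57, 352, 14)]
        env[6] = (env[6][0], 3 * env[6][1])
        fit = fit_decay(env)
        assert env[6][0] in fit.masked
        assert fit.amplitude == pytest.approx(a, rel=1e-6)
        assert fit.decay_constant == pytest.approx(lam, rel=1e-6)

    def test_refit_idempotent_on_clean_data(self):
        a, lam = 2e5, 0.01
        env = [(m, a * np.exp(-lam * m)) for m in range(57, 300, 14)]
        f1 = fit_decay(env)
        f2 = fit_decay([(p.mz, p.observed) for p in f1.fitted_points])
        assert f2.amplitude == pytest.approx(f1.amplitude, rel=1e-9)
        assert f2.decay_constant == pytest.approx(f1.decay_constant, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(DecayFitError):
            fit_decay([(57, 1.0), (71, 0.5), (85, 0.0), (99, 0.0)])


class TestDetectEnhanced:
    def test_worked_example_ions(self, methylnonacosane_clean):
        parent = determine_parent(methylnonacosane_clean)
        fit = fit_decay(extract_envelope(methylnonacosane_clean, parent),
                        parent_mz=parent.parent_mz)
        assert detect_enhanced(fit) == [141, 309]

    def test_linear_alkane_clean(self, hexacosane_clean):
        parent = determine_parent(hexacosane_clean)
        fit = fit_decay(extract_envelope(hexacosane_clean, parent),
                        parent_mz=parent.parent_mz)
        assert detect_enhanced(fit) == []

    def test_threshold_monotonicity(self, methylnonacosane_clean):
        parent = determine_parent(methylnonacosane_clean)
        fit = fit_decay(extract_envelope(methylnonacosane_clean, parent),
                        parent_mz=parent.parent_mz)
        previous = None
        for thr in (1.0, 1.5, 2.0, 2.5, 3.0, 3.5):
            hits = set(detect_enhanced(fit, ratio_threshold=thr))
            if previous is not None:
                assert hits <= previous
            previous = hits

    def test_threshold_one_returns_all_at_or_above_envelope(self, hexacosane_clean):
        parent = determine_parent(hexacosane_clean)
        fit = fit_decay(extract_envelope(hexacosane_clean, parent),
                        parent_mz=parent.parent_mz)
        expected = sorted(p.mz for p in fit.fitted_points
                          if p.observed >= p.predicted
                          and p.mz <= parent.parent_mz - 30)
        assert detect_enhanced(fit, ratio_threshold=1.0) == expected

    def test_molecular_ion_region_excluded(self):
        # enhanced ion planted at M-15 must not be reported
        a, lam, m_parent = 1e6, 0.012, 226
        env = [(m, a * np.exp(-lam * m)) for m in range(57, 212, 14)]
        env[-1] = (env[-1][0], 5 * env[-1][1])
        fit = fit_decay(env, parent_mz=m_parent)
        assert env[-1][0] == 211
        assert 211 not in detect_enhanced(fit)
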