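"""Envelope stripping, the closed-form ratios, purity inversion, extraction."""

import numpy as np
import pytest

from o18quant import (
    CorrectionRatios,
    EnvelopeMeasurement,
    LabelingModel,
    extract_envelope,
    light_ion,
    purity_correct,
    ratio_formula1,
    ratio_formula2,
    ratio_formula3,
    simulate_pair,
    strip_species,
)
from o18quant.quant import (
    SpeciesAbundances,
    envelope_ratios_for,
    purity_mixing_matrix,
)

from conftest import perfect_model


def env(i0, i2, i4, i6):
    return EnvelopeMeasurement((i0, i2, i4, i6))


def forward_channels(species, r):
    """Convolve species abundances with the natural even-channel envelope."""
    rv = [1.0, r.r2, r.r4, r.r6]
    return [
        sum(species[k] * rv[e - k] for k in range(e + 1) if e - k < len(rv))
        for e in range(4)
    ]


class TestStripSpecies:
    def test_no_overlap_is_identity(self):
        s = strip_species(env(1, 0.2, 0.5, 0.3), CorrectionRatios(0, 0, 0))
        assert s.s == (1, 0.2, 0.5, 0.3)
        assert not s.any_clamped

    def test_pure_light_cancels_exactly(self):
        r = CorrectionRatios(0.5, 0.2, 0.05)
        c = 7.3
        s = strip_species(env(c, c * 0.5, c * 0.2, c * 0.05), r)
        assert s.s0 == c
        assert s.s2 == pytest.approx(0, abs=1e-12)
        assert s.s4 == pytest.approx(0, abs=1e-12)
        assert s.s6 == pytest.approx(0, abs=1e-12)

    def test_recovers_planted_mixture(self, rng):
        """Forward-convolved random two-species mixtures invert to 1e-9."""
        for _ in range(500):
            r = CorrectionRatios(*rng.uniform(0, 0.8, 3) * [1, 0.5, 0.2])
            truth = rng.uniform(0, 10, 4)
            s = strip_species(env(*forward_channels(truth, r)), r)
            assert np.allclose(s.s, truth, atol=1e-9)

    def test_negative_channels_clamped_and_flagged(self):
        r = CorrectionRatios(0.9, 0.0, 0.0)
        s = strip_species(env(10, 1, 5, 1), r)  # I2 < r2*I0
        assert s.s2 == 0.0 and s.clamped[1]

    def test_zero_i0_rejected(self):
        with pytest.raises(ValueError):
            strip_species(env(0, 1, 1, 1), CorrectionRatios(0, 0, 0))


class TestClosedForms:
    def test_formula1_no_overlap_pure_triple(self):
        res = ratio_formula1(env(1, 0, 0, 2), CorrectionRatios(0, 0, 0))
        assert res.value == pytest.approx(0.5)
        assert res.orientation == "light/heavy"

    def test_formula1_pure_light_not_quantifiable(self, fat_ratios):
        r = fat_ratios
        res = ratio_formula1(env(1, r.r2, r.r4, r.r6), r)
        assert not res.quantifiable

    def test_formula2_trivial(self):
        assert ratio_formula2(env(1, 0, 1, 0), CorrectionRatios(0, 0, 0)).value == 1.0

    def test_formula2_pure_light_not_quantifiable(self, fat_ratios):
        r = fat_ratios
        res = ratio_formula2(env(1, r.r2, r.r4, 0), r)
        assert not res.quantifiable

    def test_closed_forms_equal_stripping_totals(self, rng):
        """Algebraic identity on 10^4 random non-clamping envelopes."""
        for _ in range(10_000):
            r = CorrectionRatios(*(rng.uniform(0, 0.7, 3) * [1, 0.6, 0.3]))
            truth = rng.uniform(0.05, 10, 4)
            e = env(*forward_channels(truth, r))
            s = strip_species(e, r)
            f1 = ratio_formula1(e, r)
            f2 = ratio_formula2(e, r)
            assert f1.value == pytest.approx(e.i0 / (s.s2 + s.s4 + s.s6), rel=1e-9)
            # formula 2 ignores I6 by construction
            assert f2.value == pytest.approx(e.i0 / (s.s2 + s.s4), rel=1e-9)

    def test_scale_invariance(self, fat_ratios):
        e1 = env(1.0, 0.6, 0.5, 1.9)
        e2 = env(*(np.array(e1.even) * 123.4))
        for f in (ratio_formula1, ratio_formula2):
            assert f(e1, fat_ratios).value == pytest.approx(f(e2, fat_ratios).value, rel=1e-12)

    def test_formula1_recovers_five_to_one_mixture(self, fat_ion, fat_ratios):
        """Noise-free 18O:16O = 5:1 inverts to 16O/18O = 0.2 exactly."""
        spectra, _ = simulate_pair(fat_ion, perfect_model(5.0), noise_cv=0, seed=0)
        e = extract_envelope(spectra, fat_ion, rt_s=600.0)
        res = ratio_formula1(e, fat_ratios)
        assert res.value == pytest.approx(0.2, abs=1e-9)

    def test_formula2_recovers_nonglyco_mixtures(self):
        ion = light_ion("ALGGEDVR", charge=2)  # no sequon: C-term labels only
        r = envelope_ratios_for(ion)
        for R in (10.0, 0.1):
            spectra, _ = simulate_pair(ion, perfect_model(R), noise_cv=0, seed=0)
            e = extract_envelope(spectra, ion, rt_s=600.0)
            assert ratio_formula2(e, r).value == pytest.approx(1 / R, abs=1e-9)

    def test_reciprocal_orientation_is_exact(self, fat_ratios):
        res = ratio_formula1(env(1, 0.6, 0.5, 1.9), fat_ratios)
        assert res.invert().value == pytest.approx(1 / res.value, rel=0)
        assert res.invert().orientation == "heavy/light"


class TestFormula3:
    def test_group_definition(self):
        s = SpeciesAbundances((1, 0, 0.5, 0.5))
        assert ratio_formula3(s).value == 1.0

    def test_single_label_switch(self):
        s = SpeciesAbundances((1, 0.3, 0.5, 0.5))
        assert ratio_formula3(s, include_single_label=True).value == pytest.approx(1.3)
        assert ratio_formula3(s, include_single_label=False).value == pytest.approx(1.0)

    def test_zero_s0_not_quantifiable(self):
        assert not ratio_formula3(SpeciesAbundances((0, 1, 1, 1))).quantifiable

    def test_complete_labeling_reconciles_with_formula1(self, fat_ion, fat_ratios):
        """With no single-label species, grouped ratio = 1/closed-form."""
        for R in (0.5, 1.0, 3.0):
            spectra, _ = simulate_pair(fat_ion, perfect_model(R, purity=1.0), noise_cv=0, seed=0)
            e = extract_envelope(spectra, fat_ion, rt_s=600.0)
            s = strip_species(e, fat_ratios)
            f3 = ratio_formula3(s)
            f1 = ratio_formula1(e, fat_ratios)
            assert f3.value == pytest.approx(R, abs=1e-9)
            assert f3.value == pytest.approx(1 / f1.value, abs=1e-9)


class TestPurity:
    def test_identity_at_full_purity(self):
        s = SpeciesAbundances((1, 2, 3, 4))
        assert purity_correct(s, 1.0) is s

    @pytest.mark.parametrize("purity", [0.97, 0.5])
    def test_binomial_forward_inverse_round_trip(self, purity, rng):
        for _ in range(100):
            truth = rng.uniform(0, 5, 4)
            m = purity_mixing_matrix(purity, 4)
            observed = m @ truth
            rec = purity_correct(SpeciesAbundances(tuple(observed)), purity)
            assert np.allclose(rec.s, truth, atol=1e-9)

    def test_pure_triple_label_mixture_inverts(self):
        p = 0.97
        observed = [p**0 * 0, 3 * p * (1 - p) ** 2, 3 * p**2 * (1 - p), p**3]
        observed[0] = (1 - p) ** 3
        rec = purity_correct(SpeciesAbundances(tuple(observed)), p)
        assert np.allclose(rec.s, [0, 0, 0, 1], atol=1e-9)

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            purity_correct(SpeciesAbundances((1, 0, 0, 0)), 0.0)


class TestExtraction:
    def test_planted_sticks_recovered_exactly(self, fat_ion):
        spectra, manifest = simulate_pair(fat_ion, perfect_model(2.0), noise_cv=0, seed=3)
        e = extract_envelope(spectra, fat_ion, rt_s=600.0)
        planted = manifest.records["FATNTTLTK"]["planted_even_channels"]
        assert np.allclose(e.even, planted[: len(e.even)], rtol=1e-9)

    def test_empty_window_flags_not_quantifiable(self, fat_ion):
        spectra, _ = simulate_pair(fat_ion, perfect_model(1.0), noise_cv=0, seed=0)
        e = extract_envelope(spectra, fat_ion, rt_s=5000.0)  # no scans there
        assert e.metadata["n_scans"] == 0 and not e.quantifiable

    def test_pair_cluster_spacing_at_z2(self):
        """Heavy and light monoisotopic positions differ by ~3.006 Th at 2+."""
        ion = light_ion("LANLTQGEDQYYLR", charge=2)
        spectra, _ = simulate_pair(ion, perfect_model(1.0, purity=1.0), noise_cv=0, seed=0)
        mz = spectra[0].mz
        inten = spectra[0].intensity
        # the two tallest sticks are the two monoisotopic peaks
        top = np.sort(mz[np.argsort(inten)[-2:]])
        assert top[1] - top[0] == pytest.approx(3.00637, abs=1e-4)

    def test_noise_robustness_at_unit_ratio(self, fat_ion, fat_ratios):
        """CV 5%: median |relative error| of recovered ratios < 10%."""
        errors = []
        model = perfect_model(1.0, purity=1.0)
        for rep in range(1000):
            spectra, _ = simulate_pair(fat_ion, model, noise_cv=0.05, n_scans=5, seed=rep)
            e = extract_envelope(spectra, fat_ion, rt_s=600.0)
            s = strip_species(e, fat_ratios)
            res = ratio_formula3(s)
            errors.append(abs(res.value - 1.0))
        assert np.median(errors) < 0.10
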