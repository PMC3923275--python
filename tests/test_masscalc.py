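"""Mass arithmetic: compositions, m/z, fragments, isotope envelopes."""

import itertools
import math

import numpy as np
import pytest

from o18quant.masscalc import (
    ATOMIC_MASSES,
    ISOTOPE_ABUNDANCES,
    O18_DELTA,
    PROTON_MASS,
    ElementalComposition,
    ModificationSpec,
    PeptideIon,
    UnknownResidueError,
    format_modifications,
    fragment_mz,
    ion_mz,
    isotope_distribution,
    label_mass_shift,
    monoisotopic_mass,
    parse_modifications,
    peptide_composition,
)


def ion(seq, mods="", charge=2, glycosites=()):
    return PeptideIon(seq, parse_modifications(mods), charge, glycosites)


class TestComposition:
    @pytest.mark.parametrize(
        "seq,mods,expected",
        [
            ("G", "", {"C": 2, "H": 5, "N": 1, "O": 2}),  # free glycine
            ("GG", "", {"C": 4, "H": 8, "N": 2, "O": 3}),  # one water lost to the bond
        ],
    )
    def test_small_peptides(self, seq, mods, expected):
        comp = peptide_composition(ion(seq, mods))
        assert dict(comp.counts) == expected

    def test_triple_label_has_three_o18(self):
        comp = peptide_composition(
            ion("FATNTTLTK", "4:Deamidation18O;cterm:2x18O", glycosites=(4,))
        )
        assert comp["O18"] == 3

    def test_arithmetic_and_negativity_guard(self):
        a = ElementalComposition({"C": 2, "H": 4})
        b = ElementalComposition({"C": 1, "H": 1})
        assert (a + b).counts == {"C": 3, "H": 5}
        assert (a - b).counts == {"C": 1, "H": 3}
        with pytest.raises(ValueError):
            b - a

    def test_unknown_residue_rejected(self):
        with pytest.raises(UnknownResidueError):
            ion("AXA")


class TestMass:
    def test_water(self):
        assert monoisotopic_mass(ElementalComposition({"H": 2, "O": 1})) == pytest.approx(
            18.010565, abs=1e-5
        )

    def test_empty_composition(self):
        assert monoisotopic_mass(ElementalComposition()) == 0.0

    def test_o18_substitution_mass(self):
        # 17.999160 - 15.994915
        assert O18_DELTA == pytest.approx(2.004246, abs=1e-6)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            monoisotopic_mass(ElementalComposition({"Zz": 1}))


class TestIonMz:
    def test_published_light_glycopeptide(self):
        """The deamidated clusterin peptide's printed 2+ m/z, within 5 ppm."""
        mz = ion_mz(ion("LANLTQGEDQYYLR", "3:Deamidation", glycosites=(3,)))
        assert abs(mz - 842.91333) / 842.91333 < 5e-6

    def test_heavy_light_spacing_is_three_label_steps(self):
        light = ion("LANLTQGEDQYYLR", "3:Deamidation", glycosites=(3,))
        heavy = ion("LANLTQGEDQYYLR", "3:Deamidation18O;cterm:2x18O", glycosites=(3,))
        assert ion_mz(heavy) - ion_mz(light) == pytest.approx(3 * O18_DELTA / 2, abs=1e-9)

    def test_singly_charged_definition(self):
        p = ion("PEPTIDE", charge=1)
        neutral = monoisotopic_mass(peptide_composition(p))
        assert ion_mz(p) == pytest.approx(neutral + PROTON_MASS, abs=1e-9)

    def test_charge_below_one_rejected(self):
        with pytest.raises(ValueError):
            PeptideIon("PEPTIDE", charge=0)


class TestLabelShift:
    @pytest.mark.parametrize(
        "g,shift,nominal",
        [(0, 4.008492, 4), (1, 6.012738, 6), (2, 8.016984, 8)],
    )
    def test_shift_values(self, g, shift, nominal):
        assert label_mass_shift(g) == pytest.approx(shift, abs=1e-5)
        assert round(label_mass_shift(g)) == nominal

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            label_mass_shift(-1)


class TestFragments:
    def test_y_step_across_labeled_site_is_117(self):
        """y12 − y11 spans the ¹⁸O-deamidated Asn: nominal 117 Da."""
        heavy = ion("LANLTQGEDQYYLR", "3:Deamidation18O;cterm:2x18O", glycosites=(3,))
        step = fragment_mz(heavy, "y", 12) - fragment_mz(heavy, "y", 11)
        assert round(step) == 117
        assert step == pytest.approx(117.03119, abs=1e-4)

    def test_cterm_label_lifts_every_y_ion_by_4(self):
        light = ion("FATNTTLTK", "4:Deamidation", glycosites=(4,))
        heavy = ion("FATNTTLTK", "4:Deamidation18O;cterm:2x18O", glycosites=(4,))
        for k in range(1, 4):  # y1..y3 exclude the site at position 4
            assert fragment_mz(heavy, "y", k) - fragment_mz(light, "y", k) == pytest.approx(
                2 * O18_DELTA, abs=1e-9
            )

    def test_b_series_shifts_only_past_the_site(self):
        light = ion("FATNTTLTK", "4:Deamidation", glycosites=(4,))
        heavy = ion("FATNTTLTK", "4:Deamidation18O;cterm:2x18O", glycosites=(4,))
        assert fragment_mz(heavy, "b", 3) == pytest.approx(fragment_mz(light, "b", 3), abs=1e-9)
        assert fragment_mz(heavy, "b", 5) - fragment_mz(light, "b", 5) == pytest.approx(
            O18_DELTA, abs=1e-9
        )

    def test_b1_definition(self):
        p = ion("GAK", charge=1)
        g_res = sum(n * ATOMIC_MASSES[el] for el, n in {"C": 2, "H": 3, "N": 1, "O": 1}.items())
        assert fragment_mz(p, "b", 1) == pytest.approx(g_res + PROTON_MASS, abs=1e-9)

    def test_complementary_fragments_sum_to_parent(self):
        p = ion("LANLTQGEDQYYLR", "3:Deamidation18O;cterm:2x18O", charge=1, glycosites=(3,))
        total = monoisotopic_mass(peptide_composition(p))
        n = len(p.sequence)
        for k in range(1, n):
            b = fragment_mz(p, "b", k) - PROTON_MASS
            y = fragment_mz(p, "y", n - k) - PROTON_MASS
            # the y fragment carries the peptide's water, so neutrals sum to M
            assert b + y == pytest.approx(total, abs=1e-6)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            fragment_mz(ion("GAK"), "y", 3)


def brute_force_envelope(counts: dict, K: int) -> np.ndarray:
    """Enumerate all isotopologue combinations (oracle for small compositions)."""
    dist = {0: 1.0}
    for el, n in counts.items():
        vec = ISOTOPE_ABUNDANCES[el]
        el_dist = {}
        # all ways to distribute n atoms over the isotopes of el
        for combo in itertools.combinations_with_replacement(range(len(vec)), n):
            ks = [combo.count(i) for i in range(len(vec))]
            w = math.factorial(n)
            for k in ks:
                w //= math.factorial(k)
            p = w * math.prod(v**k for v, k in zip(vec, ks))
            off = sum(i * k for i, k in enumerate(ks))
            el_dist[off] = el_dist.get(off, 0.0) + p
        combined: dict[int, float] = {}
        for o1, p1 in dist.items():
            for o2, p2 in el_dist.items():
                combined[o1 + o2] = combined.get(o1 + o2, 0.0) + p1 * p2
        dist = combined
    out = np.zeros(K + 1)
    for off, p in dist.items():
        if off <= K:
            out[off] += p
    return out / out.sum()


class TestIsotopeDistribution:
    def test_single_carbon(self):
        d = isotope_distribution(ElementalComposition({"C": 1}))
        assert d[0] == pytest.approx(0.9893, abs=1e-4)
        assert d[1] == pytest.approx(0.0107, abs=1e-4)

    def test_empty_composition_is_delta(self):
        d = isotope_distribution(ElementalComposition())
        assert d[0] == 1.0
        assert d.intensities[1:].sum() == 0.0

    @pytest.mark.parametrize(
        "counts",
        [
            {"C": 4, "H": 8, "N": 2, "O": 3},  # GG
            {"C": 6, "H": 12, "O": 6, "S": 1},
            {"C": 10, "H": 15, "N": 3, "O": 2},
        ],
    )
    def test_matches_brute_force_enumeration(self, counts):
        comp = ElementalComposition(counts)
        d = isotope_distribution(comp, K=8)
        oracle = brute_force_envelope(counts, K=8)
        assert np.allclose(d.intensities, oracle, atol=1e-9)

    @pytest.mark.parametrize("seq", ["FATNTTLTK", "LAPLNDSR", "ALGGEDVR", "LANLTQGEDQYYLR"])
    def test_even_ratios_decrease_for_tryptic_peptides(self, seq):
        d = isotope_distribution(peptide_composition(ion(seq)))
        assert d.ratio(6) < d.ratio(4) < d.ratio(2) < 1

    def test_added_o18_only_displaces_the_envelope(self):
        """A pure ¹⁸O atom adds a +2 mass step but no envelope structure, so
        the self-referenced distribution is unchanged — equivalently the
        light-referenced envelope shifts by exactly +2 bins per label."""
        light = peptide_composition(ion("FATNTTLTK", "4:Deamidation", glycosites=(4,)))
        labeled = light + ElementalComposition({"O18": 1})
        dl = isotope_distribution(light).intensities
        dh = isotope_distribution(labeled).intensities
        assert np.allclose(dl, dh, atol=1e-12)
        assert monoisotopic_mass(labeled) - monoisotopic_mass(light) == pytest.approx(
            ATOMIC_MASSES["O18"], abs=1e-9
        )

    def test_k_below_six_rejected(self):
        with pytest.raises(ValueError):
            isotope_distribution(ElementalComposition({"C": 1}), K=4)


class TestModificationGrammar:
    def test_round_trip(self):
        text = "4:Deamidation18O;cterm:2x18O"
        assert format_modifications(parse_modifications(text)) == text

    def test_empty_and_dash(self):
        assert parse_modifications("") == ()
        assert parse_modifications("-") == ()

    def test_unknown_modification(self):
        with pytest.raises(ValueError):
            parse_modifications("1:Phospho")

    def test_composition_mass_consistency_enforced(self):
        with pytest.raises(ValueError):
            ModificationSpec("bad", "N", 5.0, {"O": 1})

    def test_mod_position_outside_sequence(self):
        with pytest.raises(ValueError):
            ion("GAK", "9:Oxidation")
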