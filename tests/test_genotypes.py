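import pytest

from npqtau.genotypes import (
    HELD_OUT_GENOTYPES,
    TRAINING_GENOTYPES,
    compose_double_mutant,
    get_genotype,
)
from npqtau.parameters import (
    GenotypeSpec,
    KineticParameters,
    UnknownParameterError,
    apply_genotype,
)


def test_registry_ships_all_study_genotypes(truth):
    _, _, reg = truth
    expected = {"WT", "npq4", "npq1", "lut2", "zep2", "npq4npq1",
                "npq1lut2", "npq4lut2", "npq4zep2", "zep2lut2"}
    assert set(reg) == expected
    assert set(TRAINING_GENOTYPES) | set(HELD_OUT_GENOTYPES) == expected


def test_lookup_is_case_insensitive(truth):
    _, _, reg = truth
    assert get_genotype(reg, "Npq4Zep2").name == "npq4zep2"
    with pytest.raises(KeyError):
        get_genotype(reg, "npq9")


class TestApplyGenotype:
    def test_wild_type_is_identity(self, truth):
        kin, _, reg = truth
        out = apply_genotype(kin, reg["WT"])
        assert out == kin

    def test_base_is_never_mutated(self, truth):
        kin, _, reg = truth
        before = kin.as_dict()
        apply_genotype(kin, reg["npq4npq1"])
        assert kin.as_dict() == before

    def test_npq4npq1_removes_qE_and_deepoxidation(self, truth):
        kin, _, reg = truth
        out = apply_genotype(kin, reg["npq4npq1"])
        assert out.k_qvf == out.k_qaf == out.k_qzf == out.k_qlf == 0.0
        assert out.k_va == out.k_az == 0.0
        assert out.k_za == kin.k_za  # epoxidation untouched

    def test_lut2_substitutes_starred_binding_and_drops_lutein(self, truth):
        kin, _, reg = truth
        out = apply_genotype(kin, reg["lut2"])
        assert out.k_pvf == kin.k_pvf_star
        assert out.k_pzb == kin.k_pzb_star
        assert out.P_tot == kin.P_tot_star == pytest.approx(kin.P_tot / 2)
        assert out.L_tot == 0.0

    def test_zep2_scales_epoxidation_down(self, truth):
        kin, _, reg = truth
        out = apply_genotype(kin, reg["zep2"])
        assert out.k_za == pytest.approx(0.15 * kin.k_za)
        assert out.k_av == pytest.approx(0.15 * kin.k_av)

    def test_scaling_a_zeroed_rate_warns_and_zero_wins(self):
        kin = KineticParameters(k_va=0.01)
        g = GenotypeSpec(name="x", zeroed_rates=("k_va",),
                         scaled_rates=(("k_va", 2.0),))
        with pytest.warns(UserWarning, match="zero wins"):
            out = apply_genotype(kin, g)
        assert out.k_va == 0.0

    def test_unknown_rate_rejected(self):
        with pytest.raises(UnknownParameterError):
            GenotypeSpec(name="x", zeroed_rates=("k_bogus",))


class TestCompose:
    def test_wild_type_is_identity_element(self, truth):
        _, _, reg = truth
        for name in ("npq4", "lut2", "zep2"):
            c = compose_double_mutant(reg["WT"], reg[name])
            assert set(c.zeroed_rates) == set(reg[name].zeroed_rates)
            assert c.scales == reg[name].scales
            assert c.use_starred_PX == reg[name].use_starred_PX
            assert c.pigments == reg[name].pigments

    def test_commutative_on_study_genotypes(self, truth):
        _, _, reg = truth
        singles = ["npq4", "npq1", "lut2", "zep2"]
        for a in singles:
            for b in singles:
                if a == b:
                    continue
                ab = compose_double_mutant(reg[a], reg[b])
                ba = compose_double_mutant(reg[b], reg[a])
                assert ab.zeroed_rates == ba.zeroed_rates
                assert ab.scales == ba.scales
                assert ab.use_starred_PX == ba.use_starred_PX
                assert ab.pigments == pytest.approx(ba.pigments)
                assert ab.tau_dark0 == ba.tau_dark0

    def test_associative_modifications(self, truth):
        _, _, reg = truth
        a, b, c = reg["npq4"], reg["zep2"], reg["lut2"]
        left = compose_double_mutant(compose_double_mutant(a, b), c)
        right = compose_double_mutant(a, compose_double_mutant(b, c))
        assert left.zeroed_rates == right.zeroed_rates
        assert left.scales == pytest.approx(right.scales)
        assert left.use_starred_PX == right.use_starred_PX

    def test_npq1lut2_has_only_vio_qE(self, truth):
        kin, _, reg = truth
        g = reg["npq1lut2"]
        out = apply_genotype(kin, g)
        assert out.k_va == out.k_az == 0.0  # no de-epoxidation
        assert out.L_tot == 0.0  # no lutein
        assert out.k_qvf > 0  # Vio channel intact
        assert out.k_pvf == kin.k_pvf_star  # destabilized binding
        assert g.pigments["A_0"] == g.pigments["Z_0"] == 0.0

    def test_npq4zep2_keeps_dark_zea_and_short_dark_lifetime(self, truth):
        _, _, reg = truth
        g = reg["npq4zep2"]
        assert g.pigments["Z_0"] > 0
        assert g.tau_dark0 == reg["zep2"].tau_dark0 < reg["npq4"].tau_dark0

    def test_zep2lut2_expands_pool_and_keeps_zea_fraction(self, truth):
        _, _, reg = truth
        g = reg["zep2lut2"]
        vaz = sum(g.pigments[k] for k in ("V_0", "A_0", "Z_0"))
        vaz_lut2 = sum(reg["lut2"].pigments[k] for k in ("V_0", "A_0", "Z_0"))
        assert vaz == pytest.approx(vaz_lut2)  # lut2's expanded pool
        z_frac = g.pigments["Z_0"] / vaz
        vaz_zep2 = sum(reg["zep2"].pigments[k] for k in ("V_0", "A_0", "Z_0"))
        assert z_frac == pytest.approx(reg["zep2"].pigments["Z_0"] / vaz_zep2)
        assert g.pigments["L_0"] == 0.0
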