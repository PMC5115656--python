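"""BDE/IP/frontier-orbital/spin/charge descriptor computations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kynox import (AtomRecord, ReactionSystem, RecipeEntry, SpeciesRecord,
                   bde, bde_cor, build_descriptor_table, charge_descriptors,
                   homo_lumo_gap, ip, koopmans_delta, spin_delocalization,
                   thermal_correction)


def rec(label="x", energy=0.0, **kw):
    return SpeciesRecord(label=label, energy=energy, **kw)


class TestBde:
    def test_exact_cancellation(self):
        assert bde(rec("w", -100.0), rec("r", -99.5, multiplicity=2),
                   rec("H", -0.5, multiplicity=2)) == pytest.approx(0.0)

    def test_direct_sum(self):
        value = bde(rec("w", -62750.9474),
                    rec("r", -62313.0, multiplicity=2),
                    rec("H", -313.7547, multiplicity=2))
        assert value == pytest.approx(124.1927, abs=1e-9)

    def test_phase_mismatch_raises(self):
        with pytest.raises(ValueError, match="level/phase"):
            bde(rec("w", -1.0, phase="gas"),
                rec("r", -0.5, phase="water", multiplicity=2),
                rec("H", -0.5, multiplicity=2))


class TestThermalCorrection:
    def test_zero(self):
        assert thermal_correction(rec("w", 0, h_corr=0.0),
                                  rec("r", 0, h_corr=0.0, multiplicity=2),
                                  rec("H", 0, h_corr=0.0, multiplicity=2)) == 0

    def test_direct_arithmetic(self):
        h_t = thermal_correction(rec("w", 0, h_corr=80.0),
                                 rec("r", 0, h_corr=72.0, multiplicity=2),
                                 rec("H", 0, h_corr=1.48, multiplicity=2))
        assert h_t == pytest.approx(-6.52, abs=1e-12)

    def test_missing_h_corr_names_record(self):
        with pytest.raises(ValueError, match="radical.*h_corr"):
            thermal_correction(rec("w", 0, h_corr=80.0),
                               rec("radical", 0, multiplicity=2),
                               rec("H", 0, h_corr=1.48, multiplicity=2))


@pytest.mark.parametrize("bde_value, h_t, expected", [
    (106.394, -6.913, 99.481),   # phenol, corrected value of the B3LYP set
    (77.190, -5.717, 71.473),    # L-3HOK, larger-basis set
    (42.0, 0.0, 42.0),
])
def test_bde_cor(bde_value, h_t, expected):
    assert bde_cor(bde_value, h_t) == pytest.approx(expected, abs=1e-9)


class TestIp:
    def test_equal_energies(self):
        assert ip(rec("w", -5.0), rec("c", -5.0, charge=1,
                                      multiplicity=2)) == 0

    def test_planted_value(self):
        assert ip(rec("w", -1000.0),
                  rec("c", -834.572, charge=1, multiplicity=2)) == \
            pytest.approx(165.428, abs=1e-9)

    def test_anionic_parent_uses_neutral(self):
        # for an ionized-carboxyl parent the electron-abstracted form is
        # the neutral molecule: charge difference still +1
        assert ip(rec("w", -10.0, charge=-1),
                  rec("n", -5.0, charge=0, multiplicity=2)) == 5.0

    def test_wrong_charge_difference_raises(self):
        with pytest.raises(ValueError, match="charge"):
            ip(rec("w", -1.0), rec("c", -0.5))


@pytest.mark.parametrize("e_homo, e_lumo, expected", [
    (-137.424, 0.816, -138.240),    # phenol
    (-151.606, -49.448, -102.158),  # KYNA enol, gas
    (-1.0, -1.0, 0.0),
])
def test_homo_lumo_gap(e_homo, e_lumo, expected):
    gap = homo_lumo_gap(rec("x", 0, e_homo=e_homo, e_lumo=e_lumo))
    assert gap == pytest.approx(expected, abs=1e-9)


def test_homo_lumo_gap_missing_orbital_raises():
    with pytest.raises(ValueError, match="e_lumo"):
        homo_lumo_gap(rec("x", 0, e_homo=-100.0))


@pytest.mark.parametrize("ip_value, e_homo, expected", [
    (174.788, -138.366, 36.422),  # DTBP gas
    (165.428, -128.702, 36.726),  # L-3HOK gas
    (150.0, -150.0, 0.0),         # Koopmans limit
])
def test_koopmans_delta(ip_value, e_homo, expected):
    assert koopmans_delta(ip_value, e_homo) == pytest.approx(expected, abs=1e-9)


def radical_with_spins(spins):
    atoms = [AtomRecord("C", float(i), 0, 0, mulliken_spin=s)
             for i, s in enumerate(spins)]
    return rec("r", 0, multiplicity=2, atoms=atoms)


class TestSpinDelocalization:
    def test_uniform_spins_zero_dispersion(self):
        out = spin_delocalization(radical_with_spins([0.25] * 4))
        assert out["delta_sd"] == pytest.approx(0.0, abs=1e-15)

    def test_population_and_sample_conventions(self):
        r = radical_with_spins([0.9, 0.05, 0.05])
        assert spin_delocalization(r)["delta_sd"] == \
            pytest.approx(0.40069, abs=1e-5)
        assert spin_delocalization(r, convention="sample")["delta_sd"] == \
            pytest.approx(0.49075, abs=1e-5)

    def test_role_lookup(self):
        r = radical_with_spins([0.9, 0.05, 0.05])
        out = spin_delocalization(r, {"O*": 0})
        assert out["sd_by_role"]["O*"] == 0.9

    def test_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            spin_delocalization(radical_with_spins([1.0]), {"O*": 5})

    def test_missing_spin_data(self):
        atoms = [AtomRecord("C", 0, 0, 0)]
        with pytest.raises(ValueError, match="spin"):
            spin_delocalization(rec("r", 0, multiplicity=2, atoms=atoms))

    @given(spins=st.lists(st.floats(-2, 2), min_size=2, max_size=12),
           c=st.floats(-5, 5), seed=st.integers(0, 100))
    @settings(derandomize=True, max_examples=40)
    def test_permutation_invariance_and_scaling(self, spins, c, seed):
        base = spin_delocalization(radical_with_spins(spins))["delta_sd"]
        perm = np.random.default_rng(seed).permutation(spins).tolist()
        assert spin_delocalization(radical_with_spins(perm))["delta_sd"] == \
            pytest.approx(base, abs=1e-9)
        scaled = spin_delocalization(
            radical_with_spins([c * s for s in spins]))["delta_sd"]
        assert scaled == pytest.approx(abs(c) * base, rel=1e-9, abs=1e-9)


def make_system(q_reagents, q_ts, radical="phenoxyl"):
    def species(label, charges, nu=None):
        atoms = [AtomRecord("O", float(i), 0, 0, mulliken_charge=q)
                 for i, q in enumerate(charges)]
        return rec(label, 0, multiplicity=2, atoms=atoms, nu_imag=nu)
    return ReactionSystem(
        name="t", radical=radical,
        reagents=species("r", q_reagents),
        ts=species("ts", q_ts, nu=1000.0),
        products=species("p", q_ts))


class TestChargeDescriptors:
    ROLES = {"H": 0, "O1": 1, "O2": 2, "O3": 3}

    def test_all_zero(self):
        sys_ = make_system([0, 0, 0, 0], [0, 0, 0, 0])
        out = charge_descriptors(sys_, {"reagents": self.ROLES,
                                        "ts": self.ROLES})
        assert (out.q_h, out.delta_q_h, out.dq_o, out.delta_dq_ts_r) == \
            (0, 0, 0, 0)

    def test_phenoxyl_formula(self):
        sys_ = make_system([0, 0, 0, 0], [0.0, -0.35, -0.30, 0.0])
        out = charge_descriptors(sys_, {"reagents": self.ROLES,
                                        "ts": self.ROLES})
        assert out.dq_o == pytest.approx(0.05, abs=1e-12)

    def test_methyl_peroxy_formula(self):
        sys_ = make_system([0, 0, 0, 0], [0.0, -0.30, -0.20, -0.25],
                           radical="methyl_peroxy")
        out = charge_descriptors(sys_, {"reagents": self.ROLES,
                                        "ts": self.ROLES})
        assert out.dq_o == pytest.approx(-0.15, abs=1e-12)

    def test_missing_o3_for_peroxy_raises(self):
        sys_ = make_system([0, 0, 0], [0, 0, 0], radical="methyl_peroxy")
        roles = {"H": 0, "O1": 1, "O2": 2}
        with pytest.raises(ValueError, match="O3"):
            charge_descriptors(sys_, {"reagents": roles, "ts": roles})


class TestBuildDescriptorTable:
    def test_empty_recipe(self):
        assert build_descriptor_table([], []) == []

    def test_planted_round_trip(self):
        from kynox import generate_species_set
        records, truth = generate_species_set(
            5, [("L3HOK-like", 73.166, 165.428, -92.118)])
        (row,) = build_descriptor_table(
            records, [RecipeEntry("L3HOK-like", "L3HOK-like",
                                  "L3HOK-like*", "L3HOK-like+")])
        assert row.bde == pytest.approx(73.166, abs=1e-9)
        assert row.ip == pytest.approx(165.428, abs=1e-9)
        assert row.hl_gap == pytest.approx(-92.118, abs=1e-9)

    def test_missing_cation_leaves_ip_absent(self):
        from kynox import generate_species_set
        records, _ = generate_species_set(5, [("A", 80.0, 160.0, -90.0)])
        (row,) = build_descriptor_table(
            records, [RecipeEntry("A", "A", "A*", cation="missing")])
        assert row.bde is not None
        assert row.ip is None

    def test_ambiguous_label_raises(self):
        records = [rec("w", -1.0), rec("w", -2.0)]
        with pytest.raises(ValueError, match="ambiguous"):
            build_descriptor_table(records, [RecipeEntry("w", "w")])


class TestEnthalpyAssembly:
    @given(e_w=st.floats(-1e5, -1e3), d_rad=st.floats(0, 200),
           e_h=st.floats(-400, -200), h_w=st.floats(0, 100),
           h_t=st.floats(-10, 0), shift=st.floats(-1e4, 1e4))
    @settings(derandomize=True, max_examples=50)
    def test_identity_and_gauge_invariance(self, e_w, d_rad, e_h, h_w, h_t,
                                           shift):
        h_h = 1.481
        w = rec("w", e_w, h_corr=h_w)
        r = rec("r", e_w + d_rad - e_h, multiplicity=2,
                h_corr=h_w + h_t - h_h)
        h = rec("H", e_h, multiplicity=2, h_corr=h_h)
        assembled = bde_cor(bde(w, r, h), thermal_correction(w, r, h))
        direct = (r.energy + r.h_corr) + (h.energy + h.h_corr) \
            - (w.energy + w.h_corr)
        assert assembled == pytest.approx(direct, abs=1e-9)
        # gauge shift of the per-fragment reference energies: the whole
        # molecule shifts by the sum of its fragments' shifts, so the BDE
        # (a fragmentation energy) is unchanged
        w2 = rec(w.label, w.energy + 2 * shift, h_corr=w.h_corr)
        r2 = rec(r.label, r.energy + shift, h_corr=r.h_corr, multiplicity=2)
        h2 = rec(h.label, h.energy + shift, h_corr=h.h_corr, multiplicity=2)
        assert bde(w2, r2, h2) == pytest.approx(bde(w, r, h), abs=1e-8)
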