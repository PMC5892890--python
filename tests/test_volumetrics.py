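"""The volumetric particle-number equations and their identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipofrac.analytes import AVOGADRO, Analyte, ShapeModel, VolumetricConstants
from lipofrac.volumetrics import (
    SerumRecord,
    VolumetricsError,
    af4_recovery,
    analyte_per_particle,
    compute_recoveries,
    compute_sample_metrics,
    core_volume_per_liter,
    dehydrated_particle_volume,
    particle_geometry,
    particle_number,
    partition_fc,
    serum_conc_by_fraction,
    surface_volume_per_liter,
)


class TestSerumConcByFraction:
    def test_hand_arithmetic(self):
        # 10 nM in a 0.25 mL fraction, 50 uL injected, 50% recovery -> 100 nM
        assert serum_conc_by_fraction(10e-9, 0.25, 0.05, 0.5) == pytest.approx(100e-9)

    def test_identity_when_lossless_and_equal_volumes(self):
        assert serum_conc_by_fraction(3.3e-6, 0.05, 0.05, 1.0) == pytest.approx(3.3e-6)

    def test_nonpositive_recovery_rejected(self):
        with pytest.raises(VolumetricsError):
            serum_conc_by_fraction(1e-9, 0.25, 0.05, 0.0)


class TestRecovery:
    def test_sum_over_total(self):
        # fraction amounts summing to 26 pmol against a 50 pmol injection
        conc = [40e-9, 30e-9, 34e-9]  # mol/L in-fraction
        vol = [0.25, 0.25, 0.25]
        # amount = 26 pmol; serum 1 uM x 0.05 mL = 50 pmol
        assert af4_recovery(conc, vol, 1e-6, 0.05) == pytest.approx(0.52)

    def test_lossless_channel(self):
        assert af4_recovery([2e-6], [0.05], 2e-6, 0.05) == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(VolumetricsError):
            af4_recovery([1e-9], [0.25], 0.0, 0.05)


class TestFcPartition:
    def test_published_split_at_unit_lipid_ratio(self):
        """(CE+TG)/PL = 1 puts 5/6 of FC on the surface, 1/6 in the core."""
        fc_core, fc_surface, clamped = partition_fc(1.0, 0.6, 0.4, 1.0, kappa=5.0)
        assert fc_surface == pytest.approx(5.0 / 6.0, rel=1e-12)
        assert fc_core == pytest.approx(1.0 / 6.0, rel=1e-12)
        assert not clamped

    def test_no_core_lipid_puts_all_fc_on_surface(self):
        fc_core, fc_surface, _ = partition_fc(2.0, 0.0, 0.0, 1.0)
        assert fc_core == 0.0
        assert fc_surface == 2.0

    def test_direct_evaluation(self):
        fc_core, fc_surface, _ = partition_fc(6.0, 2.0, 0.0, 4.0)
        assert fc_core == pytest.approx(0.5)
        assert fc_surface == pytest.approx(5.5)

    def test_clamped_when_core_lipid_dominates(self):
        fc_core, fc_surface, clamped = partition_fc(1.0, 70.0, 0.0, 1.0, kappa=5.0)
        assert clamped
        assert fc_surface == 0.0
        assert fc_core == 1.0

    def test_zero_pl_degenerate(self):
        fc_core, fc_surface, clamped = partition_fc(1.0, 1.0, 1.0, 0.0)
        assert fc_core == 1.0 and fc_surface == 0.0 and clamped

    @given(
        fc=st.floats(0, 10), ce=st.floats(0, 10), tg=st.floats(0, 10),
        pl=st.floats(0.1, 10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mass_conserved(self, fc, ce, tg, pl):
        fc_core, fc_surface, _ = partition_fc(fc, ce, tg, pl)
        assert fc_core + fc_surface == pytest.approx(fc, rel=1e-12, abs=1e-12)
        assert fc_core >= 0 and fc_surface >= 0


class TestVolumes:
    def test_core_volume_single_ce(self, constants):
        # 1 nmol/L of CE only: 1.179e-9 * N_A nm3/L
        v = core_volume_per_liter(1e-9, 0.0, 0.0, constants)
        assert v == pytest.approx(1.179e-9 * AVOGADRO, rel=1e-12)
        assert v == pytest.approx(7.100e14, rel=1e-3)

    def test_core_volume_zero(self, constants):
        assert core_volume_per_liter(0, 0, 0, constants) == 0

    def test_surface_volume_single_protein(self, constants):
        c = constants.with_overrides(protein_mw_kda={Analyte.APOC1: 1.0})
        v = surface_volume_per_liter(0.0, 0.0, {Analyte.APOC1: 1e-9}, c)
        assert v == pytest.approx(1.212e-9 * AVOGADRO, rel=1e-12)

    def test_unknown_protein_mw_raises(self, constants):
        c = constants.with_overrides(protein_mw_kda={})
        with pytest.raises(VolumetricsError, match="A-I"):
            surface_volume_per_liter(0.0, 0.0, {Analyte.APOA1: 1e-9}, c)

    def test_dehydrated_sphere_volume(self, constants):
        # d_DLS 10.6 nm minus one 0.3 nm water layer -> d 10 nm -> (4pi/3)*5^3
        assert dehydrated_particle_volume(10.6, constants) == pytest.approx(
            523.5988, rel=1e-6
        )

    def test_ellipsoid_scales_linearly(self, constants):
        sphere = dehydrated_particle_volume(22.0, constants)
        oblate = dehydrated_particle_volume(
            22.0, constants, ShapeModel("ellipsoid", 0.5)
        )
        assert oblate == pytest.approx(0.5 * sphere, rel=1e-12)

    def test_degenerate_diameter_rejected(self, constants):
        with pytest.raises(VolumetricsError):
            dehydrated_particle_volume(0.5, constants)


class TestParticleNumber:
    def test_identity(self):
        assert particle_number(AVOGADRO * 523.6, 0.0, 523.6) == pytest.approx(1.0)

    def test_inverse_cube_scaling(self, constants):
        total = 1e15
        lp_small = particle_number(total, 0, dehydrated_particle_volume(10.6, constants))
        lp_big = particle_number(total, 0, dehydrated_particle_volume(20.6, constants))
        assert lp_small / lp_big == pytest.approx(8.0, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(VolumetricsError):
            particle_number(1.0, 1.0, 0.0)


class TestAnalytePerParticle:
    def test_unity(self):
        assert analyte_per_particle(2e-9, 2e-9) == pytest.approx(1.0)

    def test_floor_masks(self):
        assert np.isnan(analyte_per_particle(1e-9, 1e-15))

    @given(
        conc=st.floats(1e-12, 1e-3),
        ce=st.floats(0, 1e-3), tg=st.floats(0, 1e-3),
        pl=st.floats(1e-9, 1e-2), fc=st.floats(0, 1e-3),
        prot=st.floats(0, 1e-4), d=st.floats(2.0, 40.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_ratio_equals_expanded_form(self, conc, ce, tg, pl, fc, prot, d):
        """The per-particle ratio equals its algebraic expansion: the
        dehydrated particle volume times concentration over total
        constituent volume."""
        constants = VolumetricConstants()
        fc_core, fc_surface, _ = partition_fc(fc, ce, tg, pl)
        core = core_volume_per_liter(ce, tg, fc_core, constants)
        surface = surface_volume_per_liter(
            pl, fc_surface, {Analyte.APOA1: prot}, constants
        )
        pvol = dehydrated_particle_volume(d, constants)
        lp_p = particle_number(core, surface, pvol)
        via_ratio = analyte_per_particle(conc, lp_p, floor=0)
        direct = AVOGADRO * pvol * conc / (core + surface)
        assert via_ratio == pytest.approx(direct, rel=1e-9)


class TestGeometry:
    def test_equal_volumes_give_unit_ratio(self):
        d_core, thickness, ratio = particle_geometry(1e15, 1e15, 1e-6)
        assert ratio == pytest.approx(1.0)

    def test_inverse_sphere(self):
        # per-particle core volume 523.6 nm3 -> core diameter 10 nm
        lp_p = 1e-6
        core = 523.5988 * lp_p * AVOGADRO
        d_core, _, _ = particle_geometry(core, 0.0, lp_p)
        assert d_core == pytest.approx(10.0, rel=1e-6)

    def test_equal_core_surface_thickness_closed_form(self):
        lp_p = 1e-6
        core = 523.5988 * lp_p * AVOGADRO
        d_core, thickness, _ = particle_geometry(core, core, lp_p)
        d_total = 10.0 * 2.0 ** (1.0 / 3.0)
        assert thickness == pytest.approx((d_total - 10.0) / 2.0, rel=1e-6)

    def test_zero_core(self):
        lp_p = 1e-6
        surface = 523.5988 * lp_p * AVOGADRO
        d_core, thickness, ratio = particle_geometry(0.0, surface, lp_p)
        assert d_core == 0.0
        assert thickness == pytest.approx(5.0, rel=1e-6)
        assert np.isinf(ratio)


class TestSamplePipeline:
    def _toy_sample(self, rng):
        n = 10
        fractions = pd.DataFrame(
            {
                "fraction_number": np.arange(1, n + 1),
                "volume_ml": np.full(n, 0.25),
                "diameter_dls_nm": np.linspace(8, 26, n),
            }
        )
        totals = {}
        for analyte in (Analyte.APOA1, Analyte.APOB, Analyte.FC, Analyte.CE,
                        Analyte.TG, Analyte.PC, Analyte.SM):
            profile = rng.uniform(0.1, 1.0, n) * 1e-8
            fractions[analyte] = profile
            totals[analyte] = float(profile.sum() * 0.25 / 0.05 / rng.uniform(0.4, 0.9))
        serum = SerumRecord("toy", totals, injected_volume_ml=0.05)
        return fractions, serum

    def test_conservation_identity(self):
        """Recovery-corrected fraction sums reproduce the whole-serum totals
        exactly (the recovery definition makes this an identity)."""
        rng = np.random.default_rng(5)
        fractions, serum = self._toy_sample(rng)
        metrics = compute_sample_metrics(fractions, serum)
        for analyte, total in serum.total_conc_mol_l.items():
            recon = metrics[f"serum_{analyte}"].sum()
            assert recon == pytest.approx(total, rel=1e-10)

    def test_recovery_flags_suspect_values(self):
        rng = np.random.default_rng(5)
        fractions, serum = self._toy_sample(rng)
        serum.total_conc_mol_l[Analyte.APOA1] *= 100  # recovery ~ 0.005
        with pytest.warns(UserWarning, match="suspect AF4 recovery"):
            compute_recoveries(fractions, serum)

    def test_missing_diameter_excluded_from_particle_math(self):
        rng = np.random.default_rng(5)
        fractions, serum = self._toy_sample(rng)
        fractions.loc[2, "diameter_dls_nm"] = np.nan
        metrics = compute_sample_metrics(fractions, serum)
        assert metrics.loc[2, "particle_math_excluded"]
        assert np.isnan(metrics.loc[2, "lp_p_mol_l"])
        assert metrics.loc[2, "size_bin"] is None
        # but the concentration still counts towards conservation
        assert metrics[f"serum_{Analyte.PC}"].sum() == pytest.approx(
            serum.total_conc_mol_l[Analyte.PC], rel=1e-10
        )

    def test_ellipsoid_scales_every_stoichiometry_by_k(self):
        rng = np.random.default_rng(6)
        fractions, serum = self._toy_sample(rng)
        sphere = compute_sample_metrics(fractions, serum)
        oblate = compute_sample_metrics(
            fractions, serum, shape=ShapeModel("ellipsoid", 0.75)
        )
        for analyte in serum.total_conc_mol_l:
            col = f"per_particle_{analyte}"
            ratio = oblate[col] / sphere[col]
            assert np.allclose(ratio.dropna(), 0.75, rtol=1e-9)
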