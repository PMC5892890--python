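"""The synthetic generator: species construction, forward model, cohorts."""

import numpy as np
import pandas as pd
import pytest

from lipofrac.analytes import Analyte, VolumetricConstants
from lipofrac.model import VolumetricParticleModel
from lipofrac.simulate import (
    DEFAULT_CALIBRATION,
    NoiseModel,
    SERUM_DISTRIBUTIONS,
    SimulationError,
    allocate_species,
    build_species,
    default_species_library,
    draw_serum_totals,
    simulate_cohort,
    simulate_sample_profile,
)
from lipofrac.volumetrics import dehydrated_particle_volume

from conftest import LDL_LIPIDS


class TestBuildSpecies:
    def test_volume_closure_audit(self, constants):
        """Summed molecular volumes must equal the dehydrated particle volume."""
        sp = build_species("t", 20.6, {"B-100": 1}, LDL_LIPIDS, constants)
        target = dehydrated_particle_volume(20.6, constants)
        assert sp.total_volume_nm3(constants) == pytest.approx(target, rel=1e-9)

    def test_apob_copy_number_preserved(self, ldl_species):
        assert ldl_species.stoichiometry[Analyte.APOB] == 1.0

    def test_zero_lipids_rejected(self, constants):
        with pytest.raises(SimulationError):
            build_species("t", 20.6, {"B-100": 1}, {}, constants)

    def test_oversized_protein_rejected(self, constants):
        with pytest.raises(SimulationError, match="exceeds"):
            build_species("t", 8.0, {"B-100": 1}, LDL_LIPIDS, constants)

    def test_default_library_all_close(self, constants):
        for sp in default_species_library(constants):
            target = dehydrated_particle_volume(
                sp.hydrodynamic_diameter_nm, constants
            )
            assert sp.total_volume_nm3(constants) == pytest.approx(target, rel=0.01)


class TestSampleProfile:
    def test_delta_limit_single_fraction_roundtrip(self, ldl_species):
        """With zero broadening, no noise and no loss, the pipeline recovers
        the species particle number and stoichiometry exactly."""
        sp = ldl_species.with_abundance(1.2e-6)
        sample = simulate_sample_profile(
            [sp], noise=NoiseModel.noiseless(lossless=True), rng=0
        )
        occupied = sample.fractions[sample.fractions[Analyte.APOB] > 0]
        assert len(occupied) == 1
        res = VolumetricParticleModel.from_simulation(
            [sample], use_fitted_sizes=False
        ).fit()
        row = res.fraction_metrics.loc[res.fraction_metrics["lp_p_mol_l"].idxmax()]
        assert row["lp_p_mol_l"] == pytest.approx(1.2e-6, rel=1e-9)
        assert row["per_particle_B-100"] == pytest.approx(1.0, rel=1e-9)

    def test_mass_closure_with_loss(self, hdl_species):
        """Noise off: summed fraction amounts equal loss x serum amount."""
        sp = hdl_species.with_abundance(1e-5)
        sample = simulate_sample_profile([sp], noise=NoiseModel.noiseless(), rng=0)
        vinj = sample.serum.injected_volume_ml
        noise = NoiseModel.noiseless()
        for analyte, total in sample.serum.total_conc_mol_l.items():
            if total == 0:
                continue
            amount = (sample.fractions[analyte] * sample.fractions["volume_ml"]).sum()
            assert amount == pytest.approx(
                noise.loss_for(analyte) * total * vinj, rel=1e-12
            )

    def test_recovery_roundtrip_apoa1(self, hdl_species):
        """Generator loss 0.52 for apoA-I is returned exactly by the
        recovery equation when noise is off."""
        sp = hdl_species.with_abundance(1e-5)
        sample = simulate_sample_profile([sp], noise=NoiseModel.noiseless(), rng=0)
        res = VolumetricParticleModel.from_simulation([sample]).fit()
        assert res.recoveries["A-I"].iloc[0] == pytest.approx(0.52, abs=1e-6)

    def test_broadening_spreads_mass_but_conserves_it(self, ldl_species):
        import dataclasses

        sp = dataclasses.replace(
            ldl_species, broadening_sigma_nm=1.0
        ).with_abundance(1e-6)
        lossless = NoiseModel.noiseless(lossless=True)
        sample = simulate_sample_profile([sp], noise=lossless, rng=0)
        occupied = (sample.fractions[Analyte.APOB] > 0).sum()
        assert occupied > 3
        amount = (sample.fractions[Analyte.APOB] * sample.fractions["volume_ml"]).sum()
        expected = sample.serum.total_conc_mol_l[Analyte.APOB] * 0.05
        assert amount == pytest.approx(expected, rel=1e-12)

    def test_stoichiometry_at_peak_with_broadening(self, ldl_species):
        """Single species, sigma <= 1 nm: stoichiometry at the profile
        maximum recovered within 2%."""
        import dataclasses

        sp = dataclasses.replace(
            ldl_species, broadening_sigma_nm=1.0
        ).with_abundance(1e-6)
        sample = simulate_sample_profile([sp], noise=NoiseModel.noiseless(), rng=0)
        res = VolumetricParticleModel.from_simulation(
            [sample], use_fitted_sizes=False
        ).fit()
        peak = res.fraction_metrics.loc[res.fraction_metrics["lp_p_mol_l"].idxmax()]
        assert peak["per_particle_B-100"] == pytest.approx(1.0, rel=0.02)

    def test_determinism_same_seed(self, ldl_species, hdl_species):
        species = [ldl_species.with_abundance(1e-6), hdl_species.with_abundance(5e-6)]
        s1 = simulate_sample_profile(species, rng=123)
        s2 = simulate_sample_profile(species, rng=123)
        pd.testing.assert_frame_equal(s1.fractions, s2.fractions)
        pd.testing.assert_frame_equal(s1.dls, s2.dls)
        assert s1.serum.total_conc_mol_l == s2.serum.total_conc_mol_l

    def test_out_of_range_species_piles_into_terminal_fractions(self, constants):
        big = build_species(
            "huge", 60.0, {"B-100": 1}, LDL_LIPIDS, constants,
            broadening_sigma_nm=0.5,
        ).with_abundance(1e-7)
        sample = simulate_sample_profile(
            [big], noise=NoiseModel.noiseless(lossless=True), rng=0
        )
        col = sample.fractions[Analyte.APOB]
        assert col.iloc[-1] > 0
        assert col.iloc[:-1].sum() == pytest.approx(0.0, abs=col.iloc[-1] * 1e-12)


class TestCohort:
    def test_nl_total_c_calibration(self, constants):
        """Seeded NL cohort (N=25): empirical mean Total-C within two
        standard errors of the published 181 mg/dL."""
        samples = simulate_cohort({"NL": 25}, seed=1, constants=constants)
        mw = constants.lipid_mw_g_mol
        tc = [
            (s.serum.total_conc_mol_l[Analyte.FC] * mw[Analyte.FC]
             + s.serum.total_conc_mol_l[Analyte.CE] * mw[Analyte.CE]) * 100.0
            for s in samples
        ]
        mean, sd = SERUM_DISTRIBUTIONS["NL"]["Total-C"][:2]
        assert abs(np.mean(tc) - mean) <= 2 * sd / np.sqrt(25)

    def test_empty_category_is_valid(self):
        assert simulate_cohort({"NL": 0}, seed=0) == []

    def test_unknown_category_rejected(self):
        with pytest.raises(SimulationError):
            simulate_cohort({"XX": 1}, seed=0)

    def test_truth_tables_emitted(self):
        samples = simulate_cohort({"HT": 1}, seed=2)
        truth = samples[0].truth
        assert {"species", "diameter_nm", "particle_conc_mol_l"} <= set(truth.columns)
        assert (truth["particle_conc_mol_l"] > 0).all()

    def test_cohort_determinism(self):
        s1 = simulate_cohort({"NL": 2, "HL": 1}, seed=9)
        s2 = simulate_cohort({"NL": 2, "HL": 1}, seed=9)
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.fractions, b.fractions)

    def test_apob_stoichiometry_recovered_at_ldl_sizes(self):
        """Ground-truth one-apoB-per-particle recovered within 5% in the
        20-24 nm bins at default noise (cohort average)."""
        samples = simulate_cohort({"NL": 12}, seed=4)
        res = VolumetricParticleModel.from_simulation(samples).fit()
        bm = res.bin_metrics
        sub = bm[(bm["bin_lower_nm"] >= 20) & (bm["bin_lower_nm"] < 24)]
        assert sub["per_particle_B-100"].mean() == pytest.approx(1.0, rel=0.05)

    def test_allocation_matches_phenotype_totals(self, constants):
        """Species-implied Total-C tracks the drawn target within ~10%."""
        rng = np.random.default_rng(3)
        for _ in range(3):
            totals = draw_serum_totals("HC", rng, constants)
            library = default_species_library(constants, serum_totals=totals)
            species = allocate_species(totals, library)
            achieved = sum(
                sp.stoichiometry.get(a, 0.0) * sp.particle_conc_mol_l
                for sp in species
                for a in (Analyte.FC, Analyte.CE)
            )
            target = totals[Analyte.FC] + totals[Analyte.CE]
            assert achieved == pytest.approx(target, rel=0.10)


class TestHdlStoichiometry:
    def test_apoa1_per_particle_in_expected_window(self):
        """Default seeded NL cohort: apoA-I per particle at the HDL
        particle-number maximum falls in the 2-4 window."""
        samples = simulate_cohort({"NL": 25}, seed=1)
        res = VolumetricParticleModel.from_simulation(samples).fit()
        peak = res.peak_bin(8.0, 12.0)
        value = res.mean_per_particle("A-I", peak)
        assert 2.0 <= value <= 4.0
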