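"""Global SE fitting, Kd profiling and condition series."""

import dataclasses

import numpy as np
import pytest

from tetrafit.fitting import (FitSpec, NonIdentifiableError, condition_series,
                              fit_association, fit_global,
                              fit_molecular_weight, profile_kd)
from tetrafit.sedeq import (AssociationScheme, Buffer, SchemeKind, Species,
                            free_concentrations_from_totals)
from tetrafit.simulate import NoiseModel, simulate_scans


def single_scans(species, buffer, conc=5e-6, rpms=(20000, 30000, 40000),
                 noise_frac=0.0, seed=0):
    """Single-species scans; noise sd is a fraction of the mean signal."""
    scheme = AssociationScheme(SchemeKind.SINGLE, [species])
    clean = simulate_scans(scheme, [conc], rpms, buffer)
    if noise_frac == 0:
        return clean
    scale = float(np.mean([np.mean(np.abs(s.absorbance)) for s in clean]))
    return simulate_scans(scheme, [conc], rpms, buffer,
                          noise=NoiseModel(sd=noise_frac * scale, seed=seed))


class TestSingleSpeciesFits:
    def test_noiseless_mass_recovery_exact(self, pbs_cold, monomer):
        scans = single_scans(monomer, pbs_cold)
        start = dataclasses.replace(monomer, monomer_mass=22000.0)
        result = fit_molecular_weight(scans, start, pbs_cold)
        assert result.converged
        rel_err = abs(result.mass(0) - monomer.monomer_mass) / (
            monomer.monomer_mass)
        assert rel_err < 1e-6
        assert result.reduced_chi_square < 1e-12

    def test_one_percent_noise_within_five_percent(self, pbs_cold):
        species = Species("IC", 5470.0, 0.736, 40500.0)
        scans = single_scans(species, pbs_cold, noise_frac=0.01, seed=7)
        result = fit_molecular_weight(scans, species, pbs_cold)
        assert abs(result.mass(0) - 5470.0) / 5470.0 < 0.05

    def test_recovery_over_20_replicates(self, pbs_cold, monomer):
        errors = []
        for seed in range(20):
            scans = single_scans(monomer, pbs_cold, noise_frac=0.01,
                                 seed=seed)
            result = fit_molecular_weight(scans, monomer, pbs_cold)
            errors.append(abs(result.mass(0) - monomer.monomer_mass)
                          / monomer.monomer_mass)
        assert np.median(errors) < 0.02
        assert max(errors) < 0.05

    def test_zero_rpm_non_identifiable(self, pbs_cold, monomer):
        scheme = AssociationScheme(SchemeKind.SINGLE, [monomer])
        scans = simulate_scans(scheme, [5e-6], [0.0], pbs_cold)
        with pytest.raises(NonIdentifiableError):
            fit_molecular_weight(scans, monomer, pbs_cold)

    def test_dimerized_pool_apparent_mass_brackets(self, pbs_cold, monomer,
                                                   dimer_scheme):
        free = free_concentrations_from_totals(dimer_scheme, [10e-6])
        scans = simulate_scans(dimer_scheme, free, [20000, 25000, 30000],
                               pbs_cold)
        result = fit_molecular_weight(scans, monomer, pbs_cold)
        assert monomer.monomer_mass < result.mass(0) < (
            2 * monomer.monomer_mass)

    def test_duplicate_scans_same_optimum(self, pbs_cold, monomer):
        scans = single_scans(monomer, pbs_cold, noise_frac=0.01, seed=3)
        once = fit_molecular_weight(scans, monomer, pbs_cold)
        twice = fit_molecular_weight(scans + scans, monomer, pbs_cold)
        assert twice.mass(0) == pytest.approx(once.mass(0), rel=1e-6)
        assert twice.chi_square == pytest.approx(2 * once.chi_square,
                                                 rel=1e-6)

    def test_scan_order_invariance(self, pbs_cold, monomer):
        scans = single_scans(monomer, pbs_cold, noise_frac=0.01, seed=5)
        fwd = fit_molecular_weight(scans, monomer, pbs_cold)
        rev = fit_molecular_weight(scans[::-1], monomer, pbs_cold)
        assert rev.mass(0) == pytest.approx(fwd.mass(0), rel=1e-6)
        assert rev.chi_square == pytest.approx(fwd.chi_square, rel=1e-6)

    def test_reduced_chi_square_matches_noise_variance(self, pbs_cold,
                                                       monomer):
        sd = 0.005
        scheme = AssociationScheme(SchemeKind.SINGLE, [monomer])
        scans = simulate_scans(scheme, [5e-6], [20000, 25000, 30000, 35000],
                               pbs_cold, noise=NoiseModel(sd=sd, seed=11))
        result = fit_molecular_weight(scans, monomer, pbs_cold)
        assert result.reduced_chi_square == pytest.approx(sd ** 2, rel=0.2)


class TestAssociationFits:
    def test_monomer_dimer_kd_within_factor_two(self, pbs_cold, monomer,
                                                dimer_scheme):
        free = free_concentrations_from_totals(dimer_scheme, [10e-6])
        for seed in (1, 2, 3):
            scans = simulate_scans(dimer_scheme, free,
                                   [20000, 25000, 30000, 35000], pbs_cold,
                                   noise=NoiseModel(sd=0.005, seed=seed))
            result = fit_association(scans, dimer_scheme, pbs_cold,
                                     seed=seed)
            assert result.converged
            assert 20e-9 < result.kd < 80e-9

    def test_hetero_kd_within_one_decade(self, pbs_cold, hetero_scheme):
        free = free_concentrations_from_totals(hetero_scheme, [5e-6, 10e-6])
        scans = simulate_scans(hetero_scheme, free, [10000, 20000, 30000],
                               pbs_cold, noise=NoiseModel(sd=0.005, seed=2))
        result = fit_association(scans, hetero_scheme, pbs_cold, seed=2)
        assert abs(np.log10(result.kd / hetero_scheme.kd)) < 1.0

    def test_absent_association_hits_upper_bound(self, pbs_cold, monomer):
        single = AssociationScheme(SchemeKind.SINGLE, [monomer])
        scans = simulate_scans(single, [5e-6], [20000, 30000, 35000],
                               pbs_cold, noise=NoiseModel(sd=0.005, seed=3))
        scheme = AssociationScheme(SchemeKind.MONOMER_DIMER, [monomer],
                                   kd=1e-6)
        result = fit_association(scans, scheme, pbs_cold, seed=3)
        assert result.kd_at_bound

    def test_float_kd_requires_associating_scheme(self, pbs_cold, monomer):
        single = AssociationScheme(SchemeKind.SINGLE, [monomer])
        with pytest.raises(ValueError, match="associating"):
            FitSpec(scheme=single, float_kd=True)


class TestKdProfile:
    @pytest.fixture
    def noiseless_dimer_fit(self, pbs_cold, dimer_scheme):
        free = free_concentrations_from_totals(dimer_scheme, [10e-6])
        scans = simulate_scans(dimer_scheme, free, [20000, 27500, 35000],
                               pbs_cold)
        spec = FitSpec(scheme=dimer_scheme, float_kd=True, seed=1)
        return scans, spec

    def test_profile_minimum_consistent_with_best_fit(
            self, pbs_cold, noiseless_dimer_fit):
        scans, spec = noiseless_dimer_fit
        best = fit_global(scans, spec, pbs_cold)
        grid = np.logspace(np.log10(best.kd) - 1.5,
                           np.log10(best.kd) + 1.5, 9)
        grid[4] = best.kd  # evaluate the profile at the optimum itself
        profile = profile_kd(scans, spec, pbs_cold, grid=grid)
        assert profile.chi_square[4] == pytest.approx(
            best.chi_square, abs=max(1e-12, 1e-6 * best.chi_square) + 1e-9)
        assert profile.chi_square.min() >= best.chi_square - 1e-9

    def test_noiseless_profile_monotone_away_from_truth(
            self, pbs_cold, noiseless_dimer_fit):
        scans, spec = noiseless_dimer_fit
        profile = profile_kd(scans, spec, pbs_cold, n_grid=9, decades=1.5)
        imin = int(np.argmin(profile.chi_square))
        left = profile.chi_square[:imin + 1]
        right = profile.chi_square[imin:]
        assert np.all(np.diff(left) < 0)
        assert np.all(np.diff(right) > 0)

    def test_low_information_data_one_sided(self, pbs_cold, monomer):
        # weak association barely populated: only an upper bound resolves
        scheme = AssociationScheme(SchemeKind.MONOMER_DIMER, [monomer],
                                   kd=1e-4)
        free = free_concentrations_from_totals(scheme, [2e-7])
        scans = simulate_scans(scheme, free, [20000, 30000], pbs_cold,
                               noise=NoiseModel(sd=0.005, seed=4))
        spec = FitSpec(scheme=scheme, float_kd=True, seed=4, n_starts=3)
        profile = profile_kd(scans, spec, pbs_cold, n_grid=9, decades=2.0)
        assert (profile.lower is None) or (profile.upper is None)


class TestConditionSeries:
    def test_temperature_series_apparent_mass_decreases(self, pbs_cold,
                                                        monomer):
        # association weakens with temperature -> apparent mass falls
        entries = {}
        for t_c, kd in [(5.0, 2e-8), (10.0, 2e-7), (15.0, 2e-6),
                        (20.0, 2e-5)]:
            buffer = Buffer(density=1.005, temperature=t_c + 273.15)
            scheme = AssociationScheme(SchemeKind.MONOMER_DIMER, [monomer],
                                       kd=kd)
            free = free_concentrations_from_totals(scheme, [10e-6])
            entries[t_c] = (simulate_scans(scheme, free, [25000], buffer),
                            buffer)
        spec = FitSpec(scheme=AssociationScheme(SchemeKind.SINGLE, [monomer]))
        series = condition_series(entries, spec, mode="apparent_mass")
        masses = [series.summary[c] for c in series.conditions]
        assert all(a > b for a, b in zip(masses, masses[1:]))
        assert not series.failed

    def test_identical_data_identical_summaries(self, pbs_cold, monomer):
        scans = single_scans(monomer, pbs_cold, noise_frac=0.01, seed=9)
        spec = FitSpec(scheme=AssociationScheme(SchemeKind.SINGLE, [monomer]))
        series = condition_series({0.0: (scans, pbs_cold),
                                   1.0: (scans, pbs_cold)}, spec,
                                  mode="apparent_mass")
        assert series.summary[0.0] == series.summary[1.0]

    def test_salt_series_neg_log_kd_peaks_at_middle(self, pbs_cold, monomer):
        # Kd smallest (tightest) at the middle salt concentration
        entries = {}
        for nacl, kd in [(0.0, 4e-7), (0.1, 4e-9), (0.5, 4e-6)]:
            buffer = dataclasses.replace(pbs_cold, nacl=nacl)
            scheme = AssociationScheme(SchemeKind.MONOMER_DIMER, [monomer],
                                       kd=kd)
            free = free_concentrations_from_totals(scheme, [10e-6])
            entries[nacl] = (
                simulate_scans(scheme, free, [20000, 30000], buffer,
                               noise=NoiseModel(sd=0.002, seed=8)),
                buffer)
        spec = FitSpec(scheme=AssociationScheme(SchemeKind.MONOMER_DIMER,
                                                [monomer], kd=1e-7),
                       float_kd=True, seed=8)
        series = condition_series(entries, spec, mode="kd")
        neglog = [series.summary[c] for c in series.conditions]
        assert neglog[1] == max(neglog)

    def test_failed_condition_recorded_not_dropped(self, pbs_cold, monomer):
        good = single_scans(monomer, pbs_cold)
        scheme = AssociationScheme(SchemeKind.SINGLE, [monomer])
        bad = simulate_scans(scheme, [5e-6], [0.0], pbs_cold)  # no field
        spec = FitSpec(scheme=scheme)
        series = condition_series({0.0: (good, pbs_cold),
                                   1.0: (bad, pbs_cold)}, spec,
                                  mode="apparent_mass")
        assert series.failed == (1.0,)
        assert series.summary[1.0] is None
        assert series.summary[0.0] is not None
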