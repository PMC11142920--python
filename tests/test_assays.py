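"""FRET stoichiometry, micelle crowding, disulfide species
quantification, CSP computation, NIC and periodicity analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from champ.assays import (
    CrowdingModel,
    QuenchTitration,
    StoichModel,
    compute_csp,
    crowding,
    fit_stoichiometry,
    fret_theory_curve,
    half_quench_ratio,
    nic_profile,
    periodicity_fit,
    quantify_species,
)
from champ.fixtures import CSPSpec, TitrationSpec, make_csp_fixture, make_titration_fixture


class TestTheoryCurves:
    def test_dimer_half_quench_at_equimolar_ratio(self):
        model = StoichModel("dimer", 1.0, 1.0, 0.0)
        assert half_quench_ratio(model) == pytest.approx(1.0, abs=1e-9)

    def test_dimer_is_linear_in_acceptor_fraction(self):
        f = np.linspace(0, 1, 11)
        curve = fret_theory_curve(StoichModel("dimer", 0.7, 0.9), f)
        second_diff = np.diff(curve.intensity, n=2)
        assert np.allclose(second_diff, 0.0, atol=1e-12)

    def test_trimer_intensity_quarter_at_half_fraction(self):
        model = StoichModel("trimer", 1.0, 1.0, 0.0)
        assert model.intensity(np.array([0.5]))[0] == pytest.approx(0.25)

    def test_zero_acceptor_gives_unit_intensity(self):
        for stoich in ("monomer", "dimer", "trimer"):
            m = StoichModel(stoich, 1.0, 1.0, 0.5)
            assert m.intensity(np.array([0.0]))[0] == 1.0

    def test_trimer_quenches_at_least_as_much_as_dimer(self):
        f = np.linspace(0.01, 0.99, 50)
        dimer = StoichModel("dimer", 0.8, 0.9).intensity(f)
        trimer = StoichModel("trimer", 0.8, 0.9).intensity(f)
        assert np.all(trimer <= dimer + 1e-12)

    def test_acceptor_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            StoichModel("dimer").intensity(np.array([1.2]))


class TestCrowding:
    def test_reference_micelle_condition(self):
        """0.725 mM detergent (CMC 0.2, 90/micelle) with 3 uM peptide:
        175:1 micellar detergent per peptide."""
        cm = CrowdingModel(0.725, 0.2, 90, 3.0)
        assert cm.micellar_detergent_mM == pytest.approx(0.525)
        assert cm.detergent_per_peptide == pytest.approx(175.0)
        lam, co, _ = crowding(cm)
        assert lam == pytest.approx(3.0 / (1000 * 0.525 / 90))
        assert co == pytest.approx(1 - np.exp(-lam))

    def test_binder_mole_fraction_rounds_to_0p3_percent(self):
        """Equimolar binder:target at 180:1 detergent:total peptide."""
        total_peptide = 3.0  # uM
        cm = CrowdingModel(0.2 + 180 * total_peptide / 1000, 0.2, 90, total_peptide / 2)
        assert round(100 * cm.peptide_mole_fraction, 1) == 0.3

    def test_zero_peptide(self):
        cm = CrowdingModel(0.725, 0.2, 90, 0.0)
        lam, co, mf = crowding(cm)
        assert lam == 0.0 and co == 0.0 and mf == 0.0

    def test_below_cmc_rejected(self):
        with pytest.raises(ValueError, match="CMC"):
            CrowdingModel(0.1, 0.2, 90, 3.0)


class TestStoichiometryFit:
    def test_noiseless_dimer_recovered_exactly(self):
        f = np.linspace(0, 1, 9)
        y = StoichModel("dimer", 0.8, 0.95).intensity(f)
        best, fits = fit_stoichiometry(QuenchTitration(f, y))
        assert best.stoichiometry == "dimer"
        # the dimer curve is linear in f, so only the product b*E is
        # identifiable; it is recovered exactly with zero residual
        product = best.transfer_efficiency * best.bound_fraction
        assert product == pytest.approx(0.8 * 0.95, abs=1e-9)
        assert fits["dimer"].rss == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("truth", ["dimer", "trimer"])
    def test_model_recovery_on_noisy_titrations(self, truth):
        """100 synthetic titrations per model at sigma = 0.02: the
        generating stoichiometry is selected in the vast majority and
        parameters are recovered on average."""
        selected, es, bs = [], [], []
        for seed in range(100):
            df, _ = make_titration_fixture(
                TitrationSpec(stoichiometry=truth, transfer_efficiency=0.8,
                              bound_fraction=0.95, noise=0.02, seed=seed)
            )
            data = QuenchTitration(
                df.acceptor_fraction.to_numpy(), df.intensity.to_numpy()
            )
            best, _ = fit_stoichiometry(data)
            selected.append(best.stoichiometry)
            if best.stoichiometry == truth:
                es.append(best.transfer_efficiency)
                bs.append(best.bound_fraction)
        assert selected.count(truth) >= 90
        assert np.mean(np.array(es) * np.array(bs)) == pytest.approx(0.76, abs=0.03)

    def test_flat_data_selects_monomer_with_warning(self):
        f = np.linspace(0, 1, 8)
        y = np.ones_like(f)
        with pytest.warns(UserWarning, match="flat"):
            best, _ = fit_stoichiometry(QuenchTitration(f, y))
        assert best.stoichiometry == "monomer"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_stoichiometry(QuenchTitration(np.array([0, 0.5, 1.0]),
                                              np.array([1.0, 0.8, 0.6])))


class TestSpecies:
    def test_random_null_has_unit_enrichment_at_any_scale(self):
        for scale in (1.0, 37.5, 1e4):
            q = quantify_species({"AA": scale, "AB": 2 * scale, "BB": scale})
            assert q.enrichment == pytest.approx(1.0)
            assert sum(q.mole_fractions.values()) == pytest.approx(1.0)

    def test_pure_heterodimer_diverges_with_flag(self):
        q = quantify_species({"AA": 0.0, "AB": 1.0, "BB": 0.0})
        assert q.mole_fractions["AB"] == 1.0
        assert np.isinf(q.enrichment)
        assert "enrichment_divergent" in q.flags

    def test_heterodimer_dominated_mixture_matches_reported_range(self):
        """A heterodimer-dominated mixture:
        heterodimer formed at several-fold excess over the target
        homodimer."""
        q = quantify_species({"AA": 150.0, "AB": 700.0, "BB": 150.0})
        assert 2.5 <= q.heterodimer_over_aa <= 16.0
        assert q.enrichment > 1.5

    def test_extinction_weights_change_fractions(self):
        q = quantify_species({"AA": 100.0, "AB": 100.0, "BB": 100.0},
                             extinction_weights={"AA": 2.0, "AB": 1.0, "BB": 2.0})
        assert q.mole_fractions["AB"] == pytest.approx(0.5)

    def test_all_zero_areas_rejected(self):
        with pytest.raises(ValueError):
            quantify_species({"AA": 0.0, "AB": 0.0, "BB": 0.0})


class TestCSP:
    def _tables(self, deltas, n=12):
        res = np.arange(1, n + 1)
        free = pd.DataFrame({"residue": res, "atom": "CA",
                             "shift_ppm": 58.0 + 0.01 * res})
        bound = free.copy()
        bound["shift_ppm"] = bound["shift_ppm"] + deltas
        return free, bound

    def test_identical_tables_give_zero_profile(self):
        free, bound = self._tables(np.zeros(12))
        profile = compute_csp(free, bound)
        assert np.allclose(profile.table.normalized, 0.0)

    def test_single_perturbed_atom_normalizes_to_one(self):
        deltas = np.zeros(12)
        deltas[4] = 0.3
        profile = compute_csp(*self._tables(deltas))
        assert profile.table.normalized.max() == 1.0
        assert profile.table.loc[profile.table.residue == 5, "normalized"].item() == 1.0

    def test_known_pattern_recovered_exactly(self):
        deltas = np.abs(np.sin(np.arange(12)))
        profile = compute_csp(*self._tables(deltas))
        got = profile.atom_profile("CA").to_numpy()
        assert np.allclose(got, deltas / deltas.max(), atol=1e-9)

    def test_invariant_under_global_referencing_shift(self):
        deltas = np.abs(np.sin(np.arange(12)))
        free, bound = self._tables(deltas)
        base = compute_csp(free, bound).atom_profile("CA")
        free2 = free.assign(shift_ppm=free.shift_ppm + 1.7)
        bound2 = bound.assign(shift_ppm=bound.shift_ppm + 1.7)
        shifted = compute_csp(free2, bound2).atom_profile("CA")
        assert np.allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-12)

    def test_broadened_residues_flagged_not_zeroed(self):
        deltas = np.abs(np.sin(np.arange(12))) + 0.05
        free, bound = self._tables(deltas)
        profile = compute_csp(free, bound, broadened=[(3, "CA")])
        assert (3, "CA") in profile.broadened
        assert 3 not in profile.atom_profile("CA").index

    def test_duplicate_keys_rejected(self):
        free, bound = self._tables(np.zeros(12))
        dup = pd.concat([free, free.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            compute_csp(dup, bound)


class TestNIC:
    def test_distances_match_bruteforce_all_pairs(self, complex_model):
        prof = nic_profile(complex_model)
        brute = cdist(complex_model.target.ca, complex_model.binder.ca).min(axis=1)
        assert np.allclose(prof.min_distance.to_numpy(), brute)

    def test_normalization_endpoints(self, complex_model):
        prof = nic_profile(complex_model)
        core = prof.closeness.loc[prof.core_residues]
        assert core.max() == pytest.approx(1.0)
        assert core.min() == pytest.approx(0.0)

    def test_closeness_monotone_in_distance(self, complex_model):
        prof = nic_profile(complex_model)
        order = np.argsort(prof.min_distance.to_numpy())
        closeness_sorted = prof.closeness.to_numpy()[order]
        assert np.all(np.diff(closeness_sorted) <= 1e-12)

    def test_interface_maxima_at_motif_register(self, complex_model):
        """The most NIC-close target residues lie on the small-X6-small
        face the binder was placed against."""
        from champ.motifs import find_small_x6_small

        prof = nic_profile(complex_model)
        motif = find_small_x6_small(complex_model.target.sequence)[0]
        top = set(prof.closeness.sort_values(ascending=False).index[:8])
        assert len(top & set(motif.positions)) >= 2

    def test_single_helix_rejected(self, complex_model):
        from types import SimpleNamespace

        single = SimpleNamespace(
            target=complex_model.target, binder=None, frame=complex_model.frame
        )
        with pytest.raises(Exception, match="two-helix"):
            nic_profile(single)


class TestPeriodicity:
    def test_pure_cosine_period_recovered(self):
        x = np.arange(1, 26)
        y = 0.5 + 0.4 * np.cos(2 * np.pi * x / 3.6 + 0.9)
        fit = periodicity_fit(pd.Series(y, index=x))
        assert fit.period == pytest.approx(3.6, abs=0.05)
        assert fit.amplitude == pytest.approx(0.4, abs=0.01)

    def test_noisy_cosine_recovered_over_seeds(self):
        """sigma = 0.2 * amplitude noise: period recovered within the
        Monte-Carlo-derived interval across 100 seeds."""
        x = np.arange(1, 26)
        periods = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 0.5 + 0.4 * np.cos(2 * np.pi * x / 3.6) + rng.normal(0, 0.08, x.shape)
            periods.append(periodicity_fit(pd.Series(y, index=x)).period)
        assert np.mean(periods) == pytest.approx(3.6, abs=0.05)
        assert np.percentile(np.abs(np.array(periods) - 3.6), 95) < 0.15

    def test_nic_tied_pattern_correlates_in_phase(self, complex_model):
        """A CSP fixture generated from the model's own interhelical
        closeness correlates positively with NIC."""
        free, bound, truth = make_csp_fixture(
            CSPSpec(from_nic=True, noise=0.02, seed=1), model=complex_model
        )
        profile = compute_csp(free, bound)
        ca = profile.atom_profile("CA")
        nic = nic_profile(complex_model).closeness
        fit = periodicity_fit(ca, nic=nic)
        assert fit.correlation_with_nic > 0.8
        assert 3.0 <= fit.period <= 4.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            periodicity_fit(pd.Series([1.0] * 5, index=range(5)))
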