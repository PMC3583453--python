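"""Slippage + MMR model tests: closed-form expectations, Monte Carlo
agreement, genotype presets, and repair-efficiency fitting."""

from __future__ import annotations

import numpy as np
import pytest

from maturems import (
    DEFAULT_DELETION_CHANNELS,
    DEFAULT_EXPANSION_CHANNELS,
    DELETION,
    EXPANSION,
    GENOTYPE_PRESETS,
    MMRGenotype,
    PanelObservation,
    PolSlippageModel,
    RepairEfficiencies,
    expected_class_frequencies,
    fit_repair_efficiencies,
    load_gtca19_panel,
    simulate_replications,
    synth_mmr_panel,
)


def _paper_like_efficiencies() -> RepairEfficiencies:
    # Expansion (nascent-strand) repair through MutLa-containing channels;
    # deletion (template-strand) repair dominated by MutSb- and
    # MutLg-containing channels.  Magnitudes consistent with the published
    # [GT/CA]19 genotype panel.
    return RepairEfficiencies(
        {
            ("MutSa", "MutLa", EXPANSION): 0.857,
            ("MutSb", "MutLa", EXPANSION): 0.994,
            ("MutSa", "MutLg", DELETION): 0.59,
            ("MutSb", "MutLa", DELETION): 0.986,
            ("MutSb", "MutLg", DELETION): 0.975,
        }
    )


class TestGenotypes:
    def test_presets_match_cell_line_biology(self):
        assert GENOTYPE_PRESETS["LCL721"].functional_pairings == (
            ("MutSa", "MutLa"), ("MutSa", "MutLg"),
            ("MutSb", "MutLa"), ("MutSb", "MutLg"),
        )
        # PMS2-deficient: no MutLa pairings
        assert all(l != "MutLa" for _, l in GENOTYPE_PRESETS["LCL1261"].functional_pairings)
        # MSH3-deficient: no MutSb pairings
        assert all(s != "MutSb" for s, _ in GENOTYPE_PRESETS["HCT116+chr3"].functional_pairings)

    def test_hct116_has_no_channels(self):
        """MutSa subunits without any MutL complex cannot repair."""
        assert GENOTYPE_PRESETS["HCT116"].muts_alpha
        assert GENOTYPE_PRESETS["HCT116"].functional_pairings == ()


class TestExpectedClassFrequencies:
    def setup_method(self):
        self.pol = PolSlippageModel.from_point(5.6e-3, 1.2e-2)

    def test_no_repair_limit(self):
        e, d = expected_class_frequencies(
            self.pol, GENOTYPE_PRESETS["LCL721"], RepairEfficiencies(), 19
        )
        assert (e, d) == (pytest.approx(5.6e-3), pytest.approx(1.2e-2))

    def test_perfect_channel_eliminates_class(self):
        r = RepairEfficiencies({("MutSa", "MutLa", EXPANSION): 1.0})
        e, d = expected_class_frequencies(self.pol, GENOTYPE_PRESETS["LCL721"], r, 19)
        assert e == 0.0
        assert d == pytest.approx(1.2e-2)

    def test_mutl_alpha_loss_disables_mutl_alpha_only_repair(self):
        """When expansion repair requires MutLa pairings, the PMS2-deficient
        genotype reverts to the polymerase-level expansion frequency."""
        r = RepairEfficiencies(
            {("MutSa", "MutLa", EXPANSION): 0.99, ("MutSb", "MutLa", EXPANSION): 0.9}
        )
        e, _ = expected_class_frequencies(self.pol, GENOTYPE_PRESETS["LCL1261"], r, 19)
        assert e == pytest.approx(self.pol.e_exp(19))

    def test_hct116_equals_polymerase_regardless_of_r(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            r = RepairEfficiencies(
                {
                    (s, l, cls): rng.random()
                    for s in ("MutSa", "MutSb")
                    for l in ("MutLa", "MutLg")
                    for cls in (EXPANSION, DELETION)
                }
            )
            e, d = expected_class_frequencies(self.pol, GENOTYPE_PRESETS["HCT116"], r, 19)
            assert (e, d) == (pytest.approx(5.6e-3), pytest.approx(1.2e-2))

    def test_monotone_in_each_efficiency(self):
        """Raising any single r never increases its class's expected frequency."""
        rng = np.random.default_rng(1)
        genotype = GENOTYPE_PRESETS["LCL721"]
        for _ in range(20):
            base = {
                (s, l, cls): rng.random()
                for s in ("MutSa", "MutSb")
                for l in ("MutLa", "MutLg")
                for cls in (EXPANSION, DELETION)
            }
            key = list(base)[rng.integers(len(base))]
            bumped = dict(base)
            bumped[key] = min(1.0, base[key] + rng.random() * (1 - base[key]))
            f0 = expected_class_frequencies(self.pol, genotype, RepairEfficiencies(base), 19)
            f1 = expected_class_frequencies(self.pol, genotype, RepairEfficiencies(bumped), 19)
            idx = 0 if key[2] == EXPANSION else 1
            assert f1[idx] <= f0[idx] + 1e-15

    def test_length_dependence_is_exponential(self):
        pol = PolSlippageModel(1e-4, 0.3, 2e-4, 0.25)
        assert pol.e_exp(12) / pol.e_exp(10) == pytest.approx(np.exp(0.6))
        assert pol.e_del(12) / pol.e_del(10) == pytest.approx(np.exp(0.5))


class TestSimulateReplications:
    def setup_method(self):
        self.pol = PolSlippageModel.from_point(5.6e-3, 1.2e-2)

    def test_seeded_determinism(self):
        r = _paper_like_efficiencies()
        a = simulate_replications(self.pol, GENOTYPE_PRESETS["LCL721"], r, 19, 10**5, 42)
        b = simulate_replications(self.pol, GENOTYPE_PRESETS["LCL721"], r, 19, 10**5, 42)
        assert a == b
        c = simulate_replications(self.pol, GENOTYPE_PRESETS["LCL721"], r, 19, 10**5, 43)
        assert a != c

    def test_conservation(self):
        r = _paper_like_efficiencies()
        sim = simulate_replications(self.pol, GENOTYPE_PRESETS["LCL721"], r, 19, 10**5, 7)
        assert (
            sim.n_expansions + sim.n_deletions + sim.n_repaired + sim.n_error_free
            == sim.n_replications
        )
        assert sum(sim.deletion_size_counts.values()) == sim.n_deletions

    def test_no_repair_frequency_within_3se(self):
        sim = simulate_replications(
            self.pol, GENOTYPE_PRESETS["HCT116"], RepairEfficiencies(), 19, 10**6, 5
        )
        for freq, truth in ((sim.expansion_freq, 5.6e-3), (sim.deletion_freq, 1.2e-2)):
            se = np.sqrt(truth * (1 - truth) / 10**6)
            assert abs(freq - truth) <= 3 * se

    def test_perfect_repair_leaves_no_mutants(self):
        r = RepairEfficiencies(
            {
                (s, l, cls): 1.0
                for s in ("MutSa", "MutSb")
                for l in ("MutLa", "MutLg")
                for cls in (EXPANSION, DELETION)
            }
        )
        sim = simulate_replications(self.pol, GENOTYPE_PRESETS["LCL721"], r, 19, 10**5, 3)
        assert sim.n_expansions == 0 and sim.n_deletions == 0

    def test_agrees_with_closed_form_across_random_sweep(self):
        """Monte Carlo within 3 binomial SE of the expectation, 20 points."""
        rng = np.random.default_rng(123)
        n_rep = 10**6
        labels = list(GENOTYPE_PRESETS)
        for k in range(20):
            pol = PolSlippageModel.from_point(
                10 ** rng.uniform(-4, -2), 10 ** rng.uniform(-4, -2)
            )
            r = RepairEfficiencies(
                {
                    (s, l, cls): rng.uniform(0, 0.999)
                    for s in ("MutSa", "MutSb")
                    for l in ("MutLa", "MutLg")
                    for cls in (EXPANSION, DELETION)
                }
            )
            genotype = GENOTYPE_PRESETS[labels[k % 4]]
            expected = expected_class_frequencies(pol, genotype, r, 19)
            sim = simulate_replications(pol, genotype, r, 19, n_rep, int(rng.integers(2**31)))
            # exact central 99.73% binomial band: the 3-SE criterion stated
            # in a form that stays valid at small expected counts
            from scipy.stats import binom

            for count, truth in ((sim.n_expansions, expected[0]), (sim.n_deletions, expected[1])):
                lo, hi = binom.interval(0.9973, n_rep, truth)
                assert lo <= count <= hi, (count, truth)


class TestFitRepairEfficiencies:
    def setup_method(self):
        self.pol = PolSlippageModel.from_point(5.6e-3, 1.2e-2)
        self.genotypes = dict(GENOTYPE_PRESETS)

    def _random_truth(self, rng) -> RepairEfficiencies:
        # truths live on the fitter's identifiable channel structure
        r = RepairEfficiencies()
        for s, l in DEFAULT_EXPANSION_CHANNELS:
            r[(s, l, EXPANSION)] = rng.uniform(0.0, 0.995)
        for s, l in DEFAULT_DELETION_CHANNELS:
            r[(s, l, DELETION)] = rng.uniform(0.0, 0.995)
        return r

    def test_single_genotype_rejected(self):
        panel = [
            PanelObservation("LCL721", EXPANSION, 1e-5),
            PanelObservation("LCL721", DELETION, 1e-5),
        ]
        with pytest.raises(ValueError, match="single genotype"):
            fit_repair_efficiencies(panel, self.pol, 19)

    @pytest.mark.parametrize("seed", range(10))
    def test_noiseless_recovery_within_002(self, seed):
        """Each identifiable efficiency recovered within 0.02 on noiseless
        expectation panels (10 random truths)."""
        rng = np.random.default_rng(seed)
        truth = self._random_truth(rng)
        panel, _ = synth_mmr_panel(self.pol, truth, self.genotypes, 19, seed=0)
        fit = fit_repair_efficiencies(panel, self.pol, 19)
        assert not fit.rank_deficient
        for key, value in truth.as_dict().items():
            assert fit.efficiencies[key] == pytest.approx(value, abs=0.02), key

    def test_table2_panel_sign_pattern(self):
        """Fitted model predicts expansion bias for the MutLa-proficient
        lymphoblastoid lines and deletion bias for both HCT116 lines."""
        panel, pol, n = load_gtca19_panel()
        fit = fit_repair_efficiencies(panel, pol, n)
        assert fit.predicted_ratio["LCL721"] > 1
        assert fit.predicted_ratio["LCL1261"] > 1
        assert fit.predicted_ratio["HCT116+chr3"] < 1
        assert fit.predicted_ratio["HCT116"] < 1

    def test_table2_censored_bound_respected(self):
        panel, pol, n = load_gtca19_panel()
        fit = fit_repair_efficiencies(panel, pol, n)
        assert fit.predicted[("LCL1261", DELETION)] <= 1.3e-4 * (1 + 1e-6)

    def test_noisy_sign_pattern_robustness(self):
        """0.1 dex lognormal noise: the four-genotype bias sign pattern is
        recovered in >= 95% of 100 seeds."""
        truth = _paper_like_efficiencies()
        base_panel, _ = synth_mmr_panel(self.pol, truth, self.genotypes, 19, seed=0)
        expected_sign = {
            label: np.sign(np.log(ratio))
            for label, ratio in fit_repair_efficiencies(
                base_panel, self.pol, 19
            ).predicted_ratio.items()
        }
        rng = np.random.default_rng(2013)
        hits = 0
        n_seeds = 100
        for _ in range(n_seeds):
            noisy = [
                PanelObservation(
                    obs.genotype_label,
                    obs.idl_class,
                    obs.frequency * 10 ** rng.normal(0, 0.1),
                    obs.is_bound,
                    obs.genotype_override,
                )
                for obs in base_panel
            ]
            fit = fit_repair_efficiencies(noisy, self.pol, 19)
            hits += all(
                np.sign(np.log(fit.predicted_ratio[label])) == sign
                for label, sign in expected_sign.items()
            )
        assert hits / n_seeds >= 0.95

    def test_structurally_inactive_channel_flagged(self):
        """A channel functional in no panel genotype is frozen and flagged."""
        panel = [
            PanelObservation("HCT116+chr3", EXPANSION, 8.0e-4),
            PanelObservation("HCT116+chr3", DELETION, 4.9e-3),
            PanelObservation("HCT116", EXPANSION, 4.8e-3),
            PanelObservation("HCT116", DELETION, 7.3e-3),
        ]
        fit = fit_repair_efficiencies(panel, self.pol, 19)
        # no genotype here has MutSb, so MutSb channels cannot act
        assert ("MutSb", "MutLa", EXPANSION) in fit.non_identifiable
        assert fit.efficiencies[("MutSb", "MutLa", EXPANSION)] == 0.0


class TestSynthMMRPanel:
    def test_zero_efficiencies_match_polymerase_within_3se(self):
        pol = PolSlippageModel.from_point(5.6e-3, 1.2e-2)
        n_rep = 10**6
        panel, _ = synth_mmr_panel(
            pol, RepairEfficiencies(), dict(GENOTYPE_PRESETS), 19, seed=4, n_replications=n_rep
        )
        for obs in panel:
            truth = 5.6e-3 if obs.idl_class == EXPANSION else 1.2e-2
            se = np.sqrt(truth * (1 - truth) / n_rep)
            assert abs(obs.frequency - truth) <= 3 * se

    def test_paper_like_truth_reproduces_sign_pattern(self):
        pol = PolSlippageModel.from_point(5.6e-3, 1.2e-2)
        panel, _ = synth_mmr_panel(
            pol, _paper_like_efficiencies(), dict(GENOTYPE_PRESETS), 19, seed=1
        )
        freq = {(o.genotype_label, o.idl_class): o.frequency for o in panel}
        for label in ("LCL721", "LCL1261"):
            assert freq[(label, EXPANSION)] > freq[(label, DELETION)]
        for label in ("HCT116+chr3", "HCT116"):
            assert freq[(label, EXPANSION)] < freq[(label, DELETION)]

    def test_roundtrip_recovery(self):
        """Fit on a noiseless generated panel recovers the truth within 0.02."""
        pol = PolSlippageModel.from_point(5.6e-3, 1.2e-2)
        truth = _paper_like_efficiencies()
        panel, _ = synth_mmr_panel(pol, truth, dict(GENOTYPE_PRESETS), 19, seed=0)
        fit = fit_repair_efficiencies(panel, pol, 19)
        for key, value in truth.as_dict().items():
            assert fit.efficiencies[key] == pytest.approx(value, abs=0.02)
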