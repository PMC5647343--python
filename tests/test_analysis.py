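"""DFE classification, maintained beneficials, cohorts, signatures, stats."""

import numpy as np
import pytest

from driftscape import (
    Genome,
    LandscapeConfig,
    MutationClass,
    classify_mutation,
    compare_treatments,
    dfe_summary,
    dfe_table,
    epistatic_signatures,
    equal_fitness_cohorts,
    generate_landscape,
    maintained_beneficials,
)
from driftscape.analysis import bonferroni
from driftscape.evolve import GenealogyRecord, LineOfDescent
from driftscape.landscape import SyntheticLandscape


class TestClassifier:
    @pytest.mark.parametrize(
        "w_mutant,expected",
        [
            (0.0, MutationClass.lethal),
            (0.97, MutationClass.deleterious_small),
            (0.9500000001, MutationClass.deleterious_small),
            (0.95, MutationClass.deleterious_large),  # a 5% effect counts as large
            (0.5, MutationClass.deleterious_large),
            (1.0, MutationClass.neutral),
            (1.0 + 1e-14, MutationClass.neutral),
            (1.1, MutationClass.beneficial),
        ],
    )
    def test_boundaries(self, w_mutant, expected):
        assert classify_mutation(1.0, w_mutant) is expected

    def test_scales_with_parent_fitness(self):
        # s = w_m/w_0 - 1, so the boundary moves with the parent
        assert classify_mutation(2.0, 1.94) is MutationClass.deleterious_small
        assert classify_mutation(2.0, 1.90) is MutationClass.deleterious_large

    def test_nonviable_parent_rejected(self):
        with pytest.raises(ValueError):
            classify_mutation(0.0, 1.0)


def hand_built_landscape():
    """L=2, A=3 with mutant fitnesses {0, 0.99, 1.0, 1.10}."""
    factor = np.array([[1.0, 0.0, 0.99], [1.0, 1.0, 1.10]])
    return SyntheticLandscape(
        L=2,
        A=3,
        wild=np.array([0, 0]),
        site_class=("additive_small", "additive_small"),
        factor=factor,
    )


class TestDFESummary:
    def test_hand_built_fractions_and_mean(self):
        ls = hand_built_landscape()
        summ = dfe_summary(ls, ls.wild_type)
        assert summ.n_mutants == 4
        assert summ.f_lethal == summ.f_deleterious_small == 0.25
        assert summ.f_neutral == summ.f_beneficial == 0.25
        assert summ.f_deleterious_large == 0.0
        assert summ.mean_mutant_relative_fitness == pytest.approx(0.7725)

    def test_fractions_sum_to_one(self, default_landscape):
        summ = dfe_summary(default_landscape, default_landscape.wild_type)
        total = (
            summ.f_lethal
            + summ.f_deleterious_small
            + summ.f_deleterious_large
            + summ.f_neutral
            + summ.f_beneficial
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_table_classes_match_summary(self):
        ls = hand_built_landscape()
        table = dfe_table(ls, ls.wild_type)
        assert len(table) == 4
        assert set(table["class"]) == {"lethal", "deleterious_small", "neutral", "beneficial"}


def lod_from_fitness(values):
    return LineOfDescent(
        GenealogyRecord(
            gid=i, genome=Genome("A"), fitness=w, parent=i - 1, mutation=None, birth=i
        )
        for i, w in enumerate(values)
    )


class TestMaintainedBeneficials:
    def test_monotone_lod_maintains_every_beneficial_step(self):
        steps = maintained_beneficials([1.0, 1.1, 1.25, 1.5])
        assert [s.lod_index for s in steps] == [1, 2, 3]

    def test_long_dip_disqualifies_step(self):
        # five consecutive entries below the pre-step value
        w = (1, 1.2, 0.9, 0.9, 0.9, 0.9, 0.9, 1.3)
        steps = maintained_beneficials(w)
        assert [s.lod_index for s in steps] == [7]  # only the final step to 1.3

    def test_short_recovered_dip_is_transient(self):
        w = (1, 1.2, 1.1, 1.25)
        steps = maintained_beneficials(w)
        assert [s.lod_index for s in steps] == [1, 3]

    def test_four_entry_dip_is_still_transient(self):
        w = (1, 1.2, 0.9, 0.9, 0.9, 0.9, 1.3)
        steps = maintained_beneficials(w)
        assert 1 in [s.lod_index for s in steps]

    def test_maintained_steps_are_new_maxima(self):
        w = (1, 1.5, 1.2, 1.4, 1.6)
        steps = maintained_beneficials(w)
        # the step to 1.4 is beneficial but below the running maximum 1.5
        assert [s.lod_index for s in steps] == [1, 4]

    def test_running_max_baseline_option(self):
        # the step 1.2 -> 1.6 is followed by five entries at 1.3: above its
        # immediate predecessor (maintained by default) but below the
        # running maximum 1.5 (dropped under the alternative reading)
        w = (1, 1.5, 1.2, 1.6, 1.3, 1.3, 1.3, 1.3, 1.3, 1.7)
        assert 3 in [s.lod_index for s in maintained_beneficials(w)]
        assert 3 not in [
            s.lod_index for s in maintained_beneficials(w, baseline="running_max")
        ]

    def test_accepts_line_of_descent(self):
        lod = lod_from_fitness([1.0, 1.3])
        steps = maintained_beneficials(lod)
        assert len(steps) == 1 and steps[0].s_effect == pytest.approx(0.3)


class TestEqualFitnessCohorts:
    @staticmethod
    def _lineage(values, tag):
        return lod_from_fitness(values)

    def test_last_genotype_at_each_fitness_value_is_chosen(self):
        lod = lod_from_fitness([1.0, 1.5, 1.2, 1.5, 1.5])
        cohorts = equal_fitness_cohorts([lod] * 21, [lod] * 21, min_lineages=20)
        recs_small, _ = cohorts[1.5]
        assert all(rec.gid == 4 for rec in recs_small)  # the last 1.5 entry

    def test_more_than_twenty_lineages_required_on_both_sides(self):
        lod = lod_from_fitness([1.0, 1.5])
        assert 1.5 in equal_fitness_cohorts([lod] * 21, [lod] * 21)
        assert 1.5 not in equal_fitness_cohorts([lod] * 20, [lod] * 21)
        assert 1.5 not in equal_fitness_cohorts([lod] * 21, [lod] * 20)

    def test_disjoint_fitness_supports_give_empty_result(self):
        small = [lod_from_fitness([1.0, 1.2])] * 25
        large = [lod_from_fitness([1.0, 1.4])] * 25
        cohorts = equal_fitness_cohorts(small, large)
        assert 1.2 not in cohorts and 1.4 not in cohorts
        assert 1.0 in cohorts  # shared ancestor fitness still matches

    def test_relative_binning_merges_close_values(self):
        small = [lod_from_fitness([1.0, 1.5000001])] * 21
        large = [lod_from_fitness([1.0, 1.5])] * 21
        assert len(equal_fitness_cohorts(small, large, bin_rel_tol=0.0)) == 1  # ancestor only
        assert len(equal_fitness_cohorts(small, large, bin_rel_tol=1e-3)) == 2


class TestEpistaticSignatures:
    def test_modifier_toggle_converts_exact_fraction(self):
        # modifier with k=3 pure small-effect target sites; toggling it ON
        # moves exactly k*(A-1) mutants from deleterious to lethal
        cfg = LandscapeConfig(
            L=50,
            A=26,
            fractions={"additive_small": 0.30, "modifier": 0.02, "neutral": 0.68},
            beneficial_states_per_site=0,
            module_count=0,
            module_size=0,
            modifier_count=1,
            targets_per_modifier=3,
            modifier_benefit=0.04,
            extra_beneficial_sites=0,
            seed=6,
        )
        ls = generate_landscape(cfg)
        mod = ls.modifiers[0]
        on = ls.wild.copy()
        on[mod.site] = mod.on_state
        lod = LineOfDescent(
            [
                GenealogyRecord(0, ls.wild_type, 1.0, -1, None, 0),
                GenealogyRecord(
                    1,
                    Genome.from_array(on),
                    ls.fitness_of(on),
                    0,
                    (mod.site, int(ls.wild[mod.site]), mod.on_state),
                    5,
                ),
            ]
        )
        sigs = epistatic_signatures(lod, ls)
        assert len(sigs) == 1
        sig = sigs[0]
        k = len(mod.targets)
        # every mutation at the k target sites becomes lethal: exactly
        # k*(A-1) of the (A-1)*L mutants move out of the deleterious class
        assert sig.lethal_rise == pytest.approx(k * 25 / 1250, abs=1e-12)
        # the toggled modifier's own (A-1) reversion states become
        # deleterious, so the net deleterious drop is (k-1)/L
        assert sig.deleterious_drop == pytest.approx((k - 1) * 25 / 1250, abs=1e-12)
        assert sig.small_effect_share == pytest.approx(1.0)

    def test_thresholds_flag_halving_and_absolute_drop(self):
        # 15 small-effect sites (deleterious likelihood 0.30); ON converts 9
        # of them while adding its own reversion states: post 0.14, i.e. a
        # 53% relative and 0.16 absolute reduction -> both thresholds fire
        cfg = LandscapeConfig(
            L=50,
            A=26,
            fractions={"additive_small": 0.30, "modifier": 0.02, "neutral": 0.68},
            beneficial_states_per_site=0,
            module_count=0,
            module_size=0,
            modifier_count=1,
            targets_per_modifier=9,
            modifier_benefit=0.04,
            extra_beneficial_sites=0,
            seed=6,
        )
        ls = generate_landscape(cfg)
        mod = ls.modifiers[0]
        on = ls.wild.copy()
        on[mod.site] = mod.on_state
        lod = LineOfDescent(
            [
                GenealogyRecord(0, ls.wild_type, 1.0, -1, None, 0),
                GenealogyRecord(1, Genome.from_array(on), ls.fitness_of(on), 0, None, 5),
            ]
        )
        (sig,) = epistatic_signatures(lod, ls)
        assert sig.step.pre_deleterious == pytest.approx(0.30)
        assert sig.step.post_deleterious == pytest.approx(0.14)
        assert sig.relative_drop == pytest.approx(0.16 / 0.30)
        assert sig.flag_relative and sig.flag_absolute

    def test_static_dfe_yields_no_flags(self, default_landscape):
        ls = default_landscape
        neutral_site = next(i for i, c in enumerate(ls.site_class) if c == "neutral")
        g = ls.wild.copy()
        g[neutral_site] = (g[neutral_site] + 1) % ls.A
        lod = LineOfDescent(
            [
                GenealogyRecord(0, ls.wild_type, 1.0, -1, None, 0),
                GenealogyRecord(1, Genome.from_array(g), 1.0, 0, None, 1),
            ]
        )
        assert epistatic_signatures(lod, ls) == []  # neutral step is not beneficial


class TestCompareTreatments:
    def test_identical_groups_give_half_n_squared(self):
        rep = compare_treatments([1, 2, 3, 4], [1, 2, 3, 4], alternative="two-sided")
        assert rep.U == pytest.approx(8.0)  # n^2/2

    def test_fully_separated_groups_give_zero_U(self):
        rep = compare_treatments([1, 2, 3], [4, 5, 6], alternative="less")
        assert rep.U == 0.0
        # exact one-sided p for complete separation at n=3: 1 / C(6,3)
        assert rep.p_value == pytest.approx(0.05)

    def test_monotone_covariates_give_perfect_spearman(self):
        rep = compare_treatments(
            [1, 2, 3], [4, 5, 6], covariates=([1, 2, 3, 4], [10, 20, 30, 40])
        )
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compare_treatments([1, 2], [3, 4], covariates=([1, 1, 1], [1, 2, 3]))

    def test_bonferroni_caps_at_one(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.5]), [0.02, 1.0])
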