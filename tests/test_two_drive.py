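"""Male-limited homing drives versus unlinked dominant type-M resistance."""

import numpy as np
import pytest

from drivesim.core import StoppingRule
from drivesim.two_drive import (
    DriveParams,
    build_model,
    combined_suppression,
    genotype_fitness,
    initial_state,
    male_gamete_distribution,
    max_resistance_free_s,
    run_two_drive,
)

LOCI = ("A", "B", "R")
FAST = StoppingRule(max_generations=10_000)


class TestMaleGameteDistribution:
    def test_double_heterozygote_without_resistance_homes_completely(self):
        # AaBbrr with perfect drive -> only the ABr gamete
        dist = male_gamete_distribution((1, 1, 0), d=1.0, loci=LOCI)
        assert dist == {(1, 1, 0): 1.0}

    def test_resistance_is_dominant_and_restores_mendelian_segregation(self):
        # AaBbRr -> all 8 haplotypes at 1/8
        dist = male_gamete_distribution((1, 1, 1), d=1.0, loci=LOCI)
        assert len(dist) == 8
        assert all(p == pytest.approx(0.125) for p in dist.values())

    def test_imperfect_drive_acts_independently_across_loci(self):
        dist = male_gamete_distribution((1, 1, 0), d=0.9, loci=LOCI)
        assert dist[(1, 1, 0)] == pytest.approx(0.81)
        assert dist[(1, 0, 0)] == pytest.approx(0.09)
        assert dist[(0, 1, 0)] == pytest.approx(0.09)
        assert dist[(0, 0, 0)] == pytest.approx(0.01)

    def test_single_locus_rows_of_the_mating_table(self):
        # Aabbrr -> Abr, aaBbrr -> aBr
        assert male_gamete_distribution((1, 0, 0), 1.0, LOCI) == {(1, 0, 0): 1.0}
        assert male_gamete_distribution((0, 1, 0), 1.0, LOCI) == {(0, 1, 0): 1.0}


class TestGenotypeFitness:
    def test_wild_type_is_unit(self):
        p = DriveParams(s1=0.4, s2=0.3, introduction="simultaneous")
        assert genotype_fitness((0, 0, 0), p, "female", LOCI) == 1.0

    def test_double_homozygote_is_multiplicative(self):
        p = DriveParams(s1=0.4, s2=0.3, introduction="simultaneous")
        assert genotype_fitness((2, 2, 1), p, "female", LOCI) == pytest.approx(0.6 * 0.7)
        assert p.combined_s == pytest.approx(combined_suppression(0.4, 0.3))

    def test_heterozygote_cost_applies_per_locus(self):
        p = DriveParams(s1=0.4, s2=0.3, h=0.1, introduction="simultaneous")
        assert genotype_fitness((1, 1, 0), p, "female", LOCI) == pytest.approx(0.81)

    def test_resistance_is_cost_free(self):
        p = DriveParams(s1=0.4)
        assert genotype_fitness((0, 2), p, "female", ("A", "R")) == 1.0

    def test_female_limited_effects_spare_males(self):
        p = DriveParams(s1=0.4, sex_of_effect="females_only")
        assert genotype_fitness((2, 0), p, "male", ("A", "R")) == 1.0
        assert genotype_fitness((2, 0), p, "female", ("A", "R")) == pytest.approx(0.6)


class TestRunTwoDrive:
    def test_cost_free_drive_fixes_despite_resistance(self):
        params = DriveParams(s1=0.0, init_resistance=0.005)
        _, summary = run_two_drive(params, FAST)
        assert summary.outcome == "fixed"

    def test_resistance_frequency_constant_after_fixation(self):
        """Type-M resistance is neutral once the drive is fixed."""
        params = DriveParams(s1=0.2, init_drive=0.01, init_resistance=0.05)
        traj, summary = run_two_drive(params, FAST)
        assert summary.outcome == "fixed"
        r = traj.allele_series("R")
        a = traj.allele_series("A")
        post = r[a >= 1.0 - 1e-8]
        assert len(post) > 1
        assert post.max() - post.min() < 1e-7

    def test_strong_drive_fails_and_resistance_rises(self):
        params = DriveParams(s1=0.8, init_drive=0.01, init_resistance=0.05)
        traj, summary = run_two_drive(params, FAST)
        assert summary.outcome == "not_fixed"
        assert summary.final_freqs["R"] > 0.05

    def test_sequential_mode_injects_second_drive_after_trigger(self):
        params = DriveParams(s1=0.1, s2=0.1, introduction="sequential",
                             init_drive=0.005, init_resistance=0.005)
        traj, summary = run_two_drive(params, FAST)
        assert summary.outcome == "fixed"
        b = traj.allele_series("B")
        a = traj.allele_series("A")
        started = np.nonzero(b > 0)[0][0]
        assert b[0] == 0.0
        # injection happens within the generation whose post-step drive-A
        # frequency first reaches the trigger
        assert a[started] >= params.sequential_trigger
        assert a[started - 1] < params.sequential_trigger

    def test_final_resistance_nondecreasing_in_s_among_fixing_trials(self):
        """Stronger drives leave more resistance behind at fixation."""
        finals = []
        for s in (0.05, 0.15, 0.25, 0.35):
            params = DriveParams(s1=s, init_drive=0.01, init_resistance=0.005)
            _, summary = run_two_drive(params, FAST)
            assert summary.outcome == "fixed"
            finals.append(summary.final_freqs["R"])
        assert all(b >= a for a, b in zip(finals, finals[1:]))


class TestMaxResistanceFreeS:
    def test_without_resistance_only_the_intrinsic_bound_remains(self):
        """With no resistance allele, nothing blocks the drive mechanism and
        the fixation limit is the one-sex drive's intrinsic polymorphism
        bound (mean fitness floor 0.5): one grid step below s = 0.5."""
        params = DriveParams(s1=0.0, init_drive=0.01, init_resistance=0.0)
        free = max_resistance_free_s(params, grid_step=0.05)
        assert free == pytest.approx(0.45)
        withr = max_resistance_free_s(
            DriveParams(s1=0.0, init_drive=0.01, init_resistance=0.105),
            grid_step=0.05)
        assert withr < free

    def test_bisection_agrees_with_full_scan(self):
        """The fixation boundary is monotone in s, so bisection and an
        exhaustive grid scan find the same maximum."""
        params = DriveParams(s1=0.0, init_drive=0.01, init_resistance=0.05)
        fast = max_resistance_free_s(params, grid_step=0.02)
        slow = max_resistance_free_s(params, grid_step=0.02, method="scan")
        assert fast == pytest.approx(slow)

    def test_monotone_nonincreasing_in_initial_resistance(self):
        vals = []
        for r0 in (0.005, 0.105, 0.305):
            params = DriveParams(s1=0.0, init_drive=0.01, init_resistance=r0)
            vals.append(max_resistance_free_s(params))
        assert vals[0] >= vals[1] >= vals[2]

    def test_two_drives_beat_one_drive_of_equal_total_effect(self):
        one = max_resistance_free_s(
            DriveParams(s1=0.0, init_drive=0.01, init_resistance=0.005))
        two = max_resistance_free_s(
            DriveParams(s1=0.0, introduction="simultaneous",
                        init_drive=0.005, init_resistance=0.005))
        assert two >= one

    def test_sequential_and_simultaneous_agree_within_one_grid_step(self):
        seq = max_resistance_free_s(
            DriveParams(s1=0.0, introduction="sequential",
                        init_drive=0.005, init_resistance=0.105))
        sim = max_resistance_free_s(
            DriveParams(s1=0.0, introduction="simultaneous",
                        init_drive=0.005, init_resistance=0.105))
        # one 0.01 step of per-drive s moves combined s by <= 0.02 here
        assert abs(seq - sim) <= 0.021

    def test_initial_drive_frequency_robustness(self):
        """A 10x smaller introduction frequency leaves the maximum within
        one grid step."""
        base = max_resistance_free_s(
            DriveParams(s1=0.0, init_drive=0.005, init_resistance=0.105))
        low = max_resistance_free_s(
            DriveParams(s1=0.0, init_drive=0.0005, init_resistance=0.105))
        assert abs(base - low) <= 0.011


class TestDriveParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"s1": -0.1}, {"s1": 1.1}, {"s1": 0.1, "d": 0.4},
        {"s1": 0.1, "d": 1.2}, {"s1": 0.1, "sex_of_effect": "males"},
        {"s1": 0.1, "introduction": "staggered"}, {"s1": 0.1, "h": 2.0},
    ])
    def test_rejects_out_of_range(self, kwargs):
        with pytest.raises(ValueError):
            DriveParams(**kwargs)


def test_initial_state_is_product_hardy_weinberg():
    params = DriveParams(s1=0.1, init_drive=0.2, init_resistance=0.1)
    model = build_model(params)
    freq = initial_state(model, params)
    af = model.allele_freqs(freq)
    assert af[0] == pytest.approx(0.2)
    assert af[1] == pytest.approx(0.1)
    assert abs(freq.sum() - 1.0) < 1e-12
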