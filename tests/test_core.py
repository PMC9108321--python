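"""Core engine: genotype enumeration, one-generation recursion, iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivesim.core import (
    DiploidModel,
    StoppingRule,
    enumerate_genotypes,
    hardy_weinberg_state,
)
from drivesim.two_drive import DriveParams, build_model, initial_state


class TestEnumerateGenotypes:
    @pytest.mark.parametrize(
        "loci, ploidy, expected",
        [
            (("A", "B", "R"), 2, 27),  # 3 shown in the mating table + 24 Mendelian
            (("A",), 2, 3),
            (("A", "Q"), 1, 4),
            (("C", "G", "Q"), 1, 8),
        ],
    )
    def test_counts(self, loci, ploidy, expected):
        table = enumerate_genotypes(loci, ploidy=ploidy)
        assert len(table) == expected
        assert len(table.genotypes) == len(set(table.genotypes))

    def test_index_is_bijection_with_stable_lexicographic_order(self):
        table = enumerate_genotypes(("A", "B"))
        assert sorted(table.index.values()) == list(range(9))
        assert list(table.genotypes) == sorted(table.genotypes)
        assert table.label((1, 0)) == "Aabb"
        assert table.label((2, 1)) == "AABb"

    def test_rejects_duplicate_loci(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_genotypes(("A", "A"))

    def test_rejects_too_many_loci(self):
        with pytest.raises(ValueError):
            enumerate_genotypes(("A", "B", "C", "D", "E"))


def _neutral_one_locus_model():
    params = DriveParams(s1=0.0, d=0.5, init_drive=0.3, init_resistance=0.0)
    return build_model(params), params


class TestNextGeneration:
    def test_hardy_weinberg_is_stationary(self):
        """Without drive or selection, Hardy-Weinberg input reproduces itself."""
        model, params = _neutral_one_locus_model()
        freq = initial_state(model, params)
        nxt = model.next_generation(freq)
        np.testing.assert_allclose(nxt, freq, atol=1e-14)

    def test_cost_free_drive_allele_increases(self):
        params = DriveParams(s1=0.0, d=1.0, init_drive=0.1, init_resistance=0.0)
        model = build_model(params)
        freq = initial_state(model, params)
        before = model.allele_freqs(freq)[0]
        after = model.allele_freqs(model.next_generation(freq))[0]
        assert after > before

    def test_matches_brute_force_mating_enumeration(self):
        """Pooled-gamete recursion equals the exhaustive loop over
        (mother, father, egg, sperm) tuples."""
        params = DriveParams(s1=0.35, s2=0.2, d=0.9, h=0.05,
                             sex_of_effect="both", introduction="simultaneous",
                             init_drive=0.2, init_resistance=0.15)
        model = build_model(params)
        freq = initial_state(model, params)
        engine = model.next_generation(freq)

        wf = freq * model.female_fitness
        wm = freq * model.male_fitness
        wf = wf / wf.sum()
        wm = wm / wm.sum()
        haps = model.haplotypes.genotypes
        brute = np.zeros(len(model.table))
        for mi in range(len(model.table)):
            for fi in range(len(model.table)):
                pair_p = wf[mi] * wm[fi]
                if pair_p == 0:
                    continue
                for ei, egg in enumerate(haps):
                    for si, sperm in enumerate(haps):
                        p = pair_p * model.female_gametes[mi, ei] * model.male_gametes[fi, si]
                        if p == 0:
                            continue
                        child = tuple(a + b for a, b in zip(egg, sperm))
                        brute[model.table.index[child]] += p
        brute /= brute.sum()
        np.testing.assert_allclose(engine, brute, atol=1e-12)

    def test_inviable_population_raises(self):
        table = enumerate_genotypes(("A",))
        haps = enumerate_genotypes(("A",), ploidy=1)
        mendel = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])[:, ::-1]
        model = DiploidModel(table, mendel, mendel,
                             female_fitness=np.zeros(3), male_fitness=np.ones(3))
        with pytest.raises(RuntimeError, match="inviable"):
            model.next_generation(np.array([0.25, 0.5, 0.25]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=9, max_size=9),
           st.floats(0.5, 1.0), st.floats(0.0, 0.9))
    def test_conservation_and_range(self, raw, d, s):
        """Output of one generation is a probability vector for arbitrary
        normalized input states, distortion and selection."""
        params = DriveParams(s1=s, d=d, init_drive=0.1, init_resistance=0.1)
        model = build_model(params)
        freq = np.array(raw)
        freq /= freq.sum()
        out = model.next_generation(freq)
        assert abs(out.sum() - 1.0) < 1e-12
        assert np.all(out >= 0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_mendelian_limit_is_neutral(self, p, r):
        """With d = 0.5 and all fitnesses 1, allele frequencies never move."""
        params = DriveParams(s1=0.0, d=0.5, init_drive=p, init_resistance=r)
        model = build_model(params)
        freq = initial_state(model, params)
        start = model.allele_freqs(freq)
        for _ in range(5):
            freq = model.next_generation(freq)
        np.testing.assert_allclose(model.allele_freqs(freq), start, atol=1e-12)


class TestIterate:
    def test_neutral_input_stops_immediately_by_delta(self):
        model, params = _neutral_one_locus_model()
        freq = initial_state(model, params)
        _, traj = model.iterate(freq, StoppingRule(max_generations=100))
        assert traj.generations[-1] == 1

    def test_cost_free_complete_drive_reaches_fixation(self):
        params = DriveParams(s1=0.0, d=1.0, init_drive=0.01, init_resistance=0.0)
        model = build_model(params)
        stop = StoppingRule(max_generations=10_000)
        final, traj = model.iterate(initial_state(model, params), stop)
        assert model.allele_freqs(final)[0] >= stop.fixation_threshold
        assert traj.generations[-1] < 10_000

    def test_trajectory_export_roundtrip(self, tmp_path):
        params = DriveParams(s1=0.2, d=1.0, init_drive=0.05, init_resistance=0.0)
        model = build_model(params)
        _, traj = model.iterate(initial_state(model, params),
                                StoppingRule(max_generations=50))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        text = path.read_text()
        assert text.splitlines()[0] == "generation,freq_A,freq_R,mean_fitness"
        # byte-identical rerun: deterministic engine, fixed ordering
        _, traj2 = model.iterate(initial_state(model, params),
                                 StoppingRule(max_generations=50))
        path2 = tmp_path / "traj2.csv"
        traj2.to_csv(path2)
        assert path2.read_text() == text


class TestStoppingRule:
    @pytest.mark.parametrize("kwargs", [
        {"fixation_threshold": 0.0}, {"fixation_threshold": 1.0},
        {"max_generations": 0},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            StoppingRule(**kwargs)


def test_hardy_weinberg_state_matches_binomial_expansion():
    table = enumerate_genotypes(("A", "R"))
    state = hardy_weinberg_state(table, (0.3, 0.1))
    assert abs(state.sum() - 1.0) < 1e-12
    aa_rr = table.index[(0, 0)]
    assert state[aa_rr] == pytest.approx(0.49 * 0.81)
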