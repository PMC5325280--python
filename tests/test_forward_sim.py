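import numpy as np
import pytest

from isopop.forward_sim import (CrashSpec, DEFAULT_GRID, MigrationSchedule,
                                ScenarioSpec, _mate, _migrate, _mutate,
                                enumerate_grid, run_scenario,
                                supported_scenario5)
from isopop.mutation import MutationModel
from isopop.synthetic import SourceSpec


def _hwe_states(rng, n, loci, freqs):
    k = len(freqs)
    return rng.choice(k, size=(n, loci, 2), p=freqs)


class TestEngine:
    def test_drift_to_fixation_without_mutation(self):
        """mu = 0, N = 4: after 200 generations essentially all loci fix."""
        fixed = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            states = _hwe_states(rng, 4, 5, np.full(4, 0.25))
            for _ in range(200):
                states = _mate(states, rng)
            fixed.extend(
                states[:, j, :].min() == states[:, j, :].max() for j in range(5)
            )
        assert np.mean(fixed) >= 0.99

    def test_heterozygosity_decay_matches_closed_form(self):
        """E[He_t] = He_0 (1 - 1/(2N))^t for an isolated deme without mutation."""
        n, t = 50, 50
        freqs = np.full(5, 0.2)
        he0 = 1 - np.sum(freqs**2)
        finals = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            states = _hwe_states(rng, n, 8, freqs)
            for _ in range(t):
                states = _mate(states, rng)
            for j in range(8):
                flat = states[:, j, :].ravel()
                p = np.bincount(flat, minlength=5) / flat.size
                finals.append(1 - np.sum(p**2))
        expected = he0 * (1 - 1 / (2 * n)) ** t
        assert np.mean(finals) == pytest.approx(expected, rel=0.05)

    def test_migration_replaces_only_the_scheduled_sex(self):
        rng = np.random.default_rng(0)
        src = np.arange(40).reshape(20, 1, 2) + 100
        dst = np.zeros((20, 1, 2), dtype=np.int64)
        _migrate(src, dst, 5, female=True, rng=rng)
        females, males = dst[:10], dst[10:]
        assert (females > 0).any(axis=(1, 2)).sum() == 5
        assert not (males > 0).any()
        # female migrants come from the source's female half
        assert females[(females > 0).any(axis=(1, 2))].max() < 100 + 20

    def test_schedule_interpolates_linearly(self):
        s = MigrationSchedule(10.0, 0.0, 4.0, 4.0)
        assert s.at(0, 41) == (10.0, 4.0)
        assert s.at(40, 41) == (0.0, 4.0)
        assert s.at(20, 41) == (5.0, 4.0)

    @pytest.mark.parametrize("kind", ["KAM", "SMM", "TPM"])
    def test_mutation_models(self, kind):
        rng = np.random.default_rng(2)
        states = np.full((500, 10, 2), 5, dtype=np.int64)
        model = MutationModel(kind=kind, rate=0.01,
                              p_multistep=0.3 if kind == "TPM" else 0.0)
        _mutate(states, model, rng)
        changed = states[states != 5]
        assert changed.size > 0
        if kind == "KAM":
            assert changed.min() >= 0 and changed.max() < model.n_states
        if kind == "SMM":
            assert set(np.unique(changed)) <= {4, 6}
        if kind == "TPM":
            assert np.abs(changed - 5).max() >= 2  # some multi-steps


class TestScenarios:
    def test_zero_duration_returns_source_diversity(self):
        spec = ScenarioSpec("1", 100, 500, 0, MigrationSchedule(),
                            replicates=3, seed=5, sample_bp=50, sample_seon=100)
        res = run_scenario(spec)
        assert res.mean["He"] == pytest.approx(0.81, abs=0.03)
        assert abs(res.mean["Fst"]) < 0.01

    def test_determinism_under_seed(self):
        spec = ScenarioSpec("2b", 60, 300, 5,
                            MigrationSchedule.constant(1.0),
                            replicates=3, seed=7, sample_bp=30, sample_seon=60)
        assert run_scenario(spec).mean == run_scenario(spec).mean

    def test_fst_decreases_with_migration(self):
        """The migrant ladder reproduces the monotone differentiation pattern."""
        means = []
        for migrants in (0.1, 0.5, 2.0):
            spec = ScenarioSpec(
                "2b", 100, 500, 30, MigrationSchedule.constant(migrants),
                replicates=8, seed=11, sample_bp=50, sample_seon=100)
            means.append(run_scenario(spec).mean["Fst"])
        assert means[0] > means[1] > means[2]

    def test_two_migrants_keep_diversity_above_empirical(self):
        """>= 2 migrants/generation never drops deme diversity to the
        depauperate empirical level (He 0.55)."""
        spec = ScenarioSpec("2b", 100, 500, 60,
                            MigrationSchedule.constant(2.0),
                            replicates=8, seed=13, sample_bp=50,
                            sample_seon=100)
        res = run_scenario(spec)
        assert res.mean["He"] > 0.55
        assert res.mean["Na"] > 4.3

    def test_census_sizes_constant(self):
        spec = ScenarioSpec("2b", 40, 120, 3, MigrationSchedule.constant(1.0),
                            replicates=1, seed=1)
        rng = np.random.default_rng(0)
        bp = _hwe_states(rng, 40, 4, np.full(4, 0.25))
        seon = _hwe_states(rng, 120, 4, np.full(4, 0.25))
        from isopop.forward_sim import step_generation

        for g in range(3):
            bp, seon = step_generation(bp, seon, spec, g, rng)
        assert bp.shape[0] == 40 and seon.shape[0] == 120

    def test_excess_scheduled_migration_rejected(self):
        with pytest.raises(ValueError, match="migrants exceed"):
            ScenarioSpec("1", 10, 100, 5, MigrationSchedule.constant(20.0))

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ScenarioSpec("9", 100, 500, 5, MigrationSchedule())


class TestGrid:
    def test_published_counts(self):
        specs = enumerate_grid()
        by = {}
        for s in specs:
            by[s.scenario] = by.get(s.scenario, 0) + 1
        assert by["3"] == 13
        assert by["4"] == 16
        assert by["5"] == by["3"] * by["4"] == 208
        assert by["1"] + by["2a"] + by["2b"] == 52
        assert len(specs) == 289

    def test_empty_config_gives_empty_grid(self):
        cfg = {"densities": [], "scenario3_crashes": [],
               "scenario4_final_migrants": []}
        assert enumerate_grid(cfg) == []

    def test_duplicates_deduplicated_with_warning(self):
        cfg = {"scenario2b_migrants": [1.0, 1.0]}
        with pytest.warns(UserWarning, match="duplicate"):
            specs = enumerate_grid(cfg)
        assert len({(s.scenario, s.n_bp, s.generations, s.migration, s.crash)
                    for s in specs}) == len(specs)


class TestCrashScenario:
    def test_supported_set_reproduces_depauperate_deme(self):
        """The recent-isolation + two-crash history lands on the empirical
        diversity/differentiation neighbourhood."""
        res = run_scenario(supported_scenario5(seed=3, replicates=12))
        assert 3.8 <= res.mean["Na"] <= 4.7
        assert 0.08 <= res.mean["Fst"] <= 0.16
        assert abs(res.mean["Fis_nei"]) < 0.05

    def test_scenario3_requires_crash(self):
        with pytest.raises(ValueError, match="crash"):
            ScenarioSpec("3", 220, 2200, 11, MigrationSchedule())
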