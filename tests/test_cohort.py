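"""Dixon's Q screening, Monte-Carlo critical values, cohort construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import catpot as cp
from catpot import (
    CohortSpec,
    OutlierSpec,
    build_cohort,
    dixon_critical_value,
    dixon_q,
    generate_cohort,
    sample_feasible_state,
    screen_outlier_percs,
)

# two-sided r10 critical values (Rorabacher 1991), used as the published
# reference for the Monte-Carlo estimator
R10_TWO_SIDED = {
    0.95: {4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493, 10: 0.466},
    0.99: {4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680, 8: 0.634, 9: 0.598, 10: 0.568},
}


class TestDixonQ:
    def test_textbook_example(self):
        q, idx = dixon_q([1.0, 2.0, 3.0, 10.0])
        assert q == pytest.approx(7.0 / 9.0)
        assert idx == 3

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="zero range"):
            dixon_q([2.0, 2.0, 2.0, 2.0])

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            dixon_q([1.0, 2.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=12, unique=True))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_by_definition(self, values):
        """Independent oracle: gap to nearest neighbour of the point farthest
        from the median, over the full range."""
        x = np.array(values)
        med = np.median(x)
        suspect = int(np.argmax(np.abs(x - med)))
        gap = min(abs(v - x[suspect]) for i, v in enumerate(x) if i != suspect)
        expected = gap / (x.max() - x.min())
        q, idx = dixon_q(x)
        assert q == pytest.approx(expected)
        assert 0.0 <= q <= 1.0


class TestCriticalValue:
    @pytest.mark.parametrize("confidence", [0.95, 0.99])
    def test_matches_published_two_sided_tables(self, confidence):
        for n, expected in R10_TWO_SIDED[confidence].items():
            got = dixon_critical_value(n, confidence, reps=200_000, rng_seed=11)
            assert got == pytest.approx(expected, abs=0.01)

    def test_small_n_approaches_one(self):
        assert dixon_critical_value(3, 0.99, reps=100_000, rng_seed=3) > 0.97

    def test_deterministic_under_seed(self):
        a = dixon_critical_value(9, 0.99, reps=50_000, rng_seed=5)
        b = dixon_critical_value(9, 0.99, reps=50_000, rng_seed=5)
        assert a == b

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dixon_critical_value(2, 0.99)
        with pytest.raises(ValueError):
            dixon_critical_value(9, 1.5)


class TestFeasibleSampling:
    def test_no_thermodynamic_constraint_accepts_first_draw(self, nominal_ref):
        ranges = {s: (v / 2, v * 2) for s, v in nominal_ref.concentrations.items()
                  if s in ("g6p", "f6p")}
        keqs = {"R": np.inf}
        ref = sample_feasible_state(ranges, keqs, {"R": 1.0}, rng_seed=0,
                                    nominal=nominal_ref)
        assert ref.source == "randomized:0"

    def test_infeasible_box_raises_after_max_attempts(self, nominal_ref):
        # A -> B with Keq below every reachable mass-action ratio
        ranges = {"g6p": (10.0, 20.0), "f6p": (30.0, 40.0)}
        keqs = dict(nominal_ref.keqs)
        keqs["PGI"] = 1.0  # Gamma = f6p/g6p >= 1.5 > Keq always
        with pytest.raises(cp.ModelStructureError, match="attempts"):
            sample_feasible_state(ranges, keqs, {"PGI": 1.0}, rng_seed=0,
                                  nominal=nominal_ref, max_attempts=200)

    def test_deterministic_under_seed(self, nominal_ref):
        a = cp.randomized_reference(seed=123, nominal=nominal_ref)
        b = cp.randomized_reference(seed=123, nominal=nominal_ref)
        assert a.concentrations == b.concentrations

    def test_sampled_states_parameterize_and_satisfy_feasibility(self, nominal_ref):
        from catpot.synth import feasibility_ok

        for seed in range(5):
            ref = cp.randomized_reference(seed=seed, nominal=nominal_ref)
            assert all(feasibility_ok(ref, rid) for rid in ref.fluxes)
            model = cp.build_rbc_model(ref, ("PFK",))
            assert cp.verify_steady_state(model).passed


class TestCohort:
    def test_empty_cohort(self):
        table = build_cohort([])
        assert table.individuals == []

    def test_screening_needs_three_individuals(self):
        inds = generate_cohort(CohortSpec(n=2, seed=0))
        table = build_cohort(inds)
        with pytest.raises(ValueError, match="at least 3"):
            screen_outlier_percs(table)

    def test_randomized_cohort_parameterizes(self, nominal_ref):
        inds = [
            cp.Individual(f"R{i}", f"R{i}", cp.randomized_reference(seed=i, nominal=nominal_ref))
            for i in range(6)
        ]
        table = build_cohort(inds)
        assert len(table.individuals) == 6
        assert table.perc_matrix().shape[1] == 6

    def test_outlier_recovery_identifies_parameters_and_individual(self):
        spec = CohortSpec(n=9, sigma=0.2,
                          outlier=OutlierSpec(individual_index=2), seed=1)
        table = build_cohort(generate_cohort(spec))
        results = screen_outlier_percs(table, critical_value=0.598)
        flagged = {r.parameter: r for r in results if r.outlier}
        assert any(p.startswith("PFK_BIND_ATP") for p in flagged)
        assert any(p.startswith("PFK_BIND_F6P") for p in flagged)
        for p, r in flagged.items():
            if p.startswith("PFK_BIND"):
                assert r.suspect == "Individual #3"

    def test_null_cohort_module_constants_not_flagged(self):
        """Without an injected outlier the module binding constants are
        identical across individuals and are skipped, not flagged."""
        table = build_cohort(generate_cohort(CohortSpec(n=9, sigma=0.2, seed=4)))
        results = screen_outlier_percs(table, critical_value=0.598)
        binding = [r for r in results if r.parameter.startswith("PFK_BIND")]
        assert binding and all("skipped" in r.note for r in binding)
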