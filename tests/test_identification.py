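"""Candidate fitting, rational-ODE reconstruction, simulation, scoring."""

import numpy as np
import pytest

from sindypi.identification import (CandidateModel, DegenerateLhsError,
                                    NotReducibleError, RationalODE,
                                    derivative_candidates, fit_candidate,
                                    simulate_identified, structure_error,
                                    sweep_candidates, to_explicit_ode)
from sindypi.library import (TermDescriptor, TimeSeriesData, enumerate_terms,
                             evaluate_terms)
from sindypi.solvers import SolverConfig
from sindypi import systems

MM = systems.MMParams()


def mm_true_rhs(x):
    return MM.j_x - MM.V_max * x / (MM.K_m + x)


class TestFitCandidate:
    def test_noiseless_mm_matches_cleared_relation(self, mm_library):
        j = mm_library.column("dx*x")
        model = fit_candidate(mm_library, j, SolverConfig(threshold=0.1))
        # dx*x = -K_m dx + j_x K_m + (j_x - V_max) x
        coefs = {t.label: c for t, c in zip(model.terms, model.coefficients)
                 if c != 0.0}
        assert set(coefs) == {"dx", "1", "x"}
        assert np.isclose(coefs["dx"], -MM.K_m, rtol=1e-6)
        assert np.isclose(coefs["1"], MM.j_x * MM.K_m, rtol=1e-6)
        assert np.isclose(coefs["x"], MM.j_x - MM.V_max, rtol=1e-6)

    def test_degenerate_zero_lhs_raises(self):
        data = TimeSeriesData(t=np.arange(10.0),
                              X=np.column_stack([np.ones(10), np.zeros(10)]),
                              Xdot=np.ones((10, 2)),
                              state_names=("x", "z"))
        terms = [TermDescriptor((("x", 1),)), TermDescriptor((("z", 1),)),
                 TermDescriptor((("dx", 1),))]
        lib = evaluate_terms(terms, data)
        with pytest.raises(DegenerateLhsError, match="degenerate"):
            fit_candidate(lib, 1, SolverConfig(threshold=0.1))

    def test_wrong_candidate_fits_much_worse(self, mm_data):
        # in the cofactor-capped library {1, x, x^2, dx, dx*x} the term x^2
        # participates in no exact implicit relation, so using it as the
        # left-hand side must leave a large residual at every threshold
        from sindypi.library import LibrarySpec
        spec = LibrarySpec(state_names=("x",), degree=2,
                           deriv_cofactor_degree=1)
        lib = evaluate_terms(enumerate_terms(spec), mm_data)
        cfg = SolverConfig(threshold=0.1)
        good = fit_candidate(lib, lib.column("dx*x"), cfg)
        bad_resids = []
        for lam in np.arange(0.1, 1.01, 0.1):
            bad = fit_candidate(lib, lib.column("x^2"),
                                SolverConfig(threshold=float(lam)))
            bad_resids.append(bad.residual)
        assert min(bad_resids) >= 10 * max(good.residual, 1e-12)


class TestSweep:
    def test_cardinality(self, mm_library):
        models = sweep_candidates(mm_library, [1, 2, 3, 4, 5],
                                  [0.1, 0.2, 0.3, 0.4],
                                  SolverConfig(threshold=0.1))
        assert len(models) == 20

    def test_parallel_matches_sequential_bitwise(self, mm_library):
        cands = derivative_candidates(mm_library, "dx")
        lams = [0.1, 0.5]
        seq = sweep_candidates(mm_library, cands, lams,
                               SolverConfig(threshold=0.1), n_jobs=1)
        par = sweep_candidates(mm_library, cands, lams,
                               SolverConfig(threshold=0.1), n_jobs=2)
        for a, b in zip(seq, par):
            assert a.lhs.label == b.lhs.label
            assert np.array_equal(a.coefficients, b.coefficients)

    def test_derivative_candidate_filter(self, mm_library):
        cands = derivative_candidates(mm_library, "dx")
        labels = [mm_library.terms[i].label for i in cands]
        assert labels == ["dx", "dx*x", "dx*x^2"]
        for i in cands:
            assert mm_library.terms[i].exponent("dx") == 1

    def test_failures_captured_not_raised(self):
        data = TimeSeriesData(t=np.arange(10.0),
                              X=np.column_stack([np.ones(10), np.zeros(10)]),
                              Xdot=np.ones((10, 2)),
                              state_names=("x", "z"))
        terms = [TermDescriptor((("x", 1),)), TermDescriptor((("z", 1),)),
                 TermDescriptor((("dx", 1),))]
        lib = evaluate_terms(terms, data)
        models = sweep_candidates(lib, [0, 1], [0.1],
                                  SolverConfig(threshold=0.1))
        assert not models[0].failed
        assert models[1].failed and "degenerate" in models[1].error

    def test_empty_candidate_set_rejected(self, mm_library):
        with pytest.raises(ValueError):
            sweep_candidates(mm_library, [], [0.1],
                             SolverConfig(threshold=0.1))


class TestToExplicit:
    def test_mm_rational_form_matches_truth_pointwise(self, mm_library):
        model = fit_candidate(mm_library, mm_library.column("dx*x"),
                              SolverConfig(threshold=0.1))
        ode = to_explicit_ode(model, "x", train_data=mm_library.source)
        rng = np.random.default_rng(0)
        xs = rng.uniform(0.05, 2.0, 100)
        for x in xs:
            assert np.isclose(ode.rhs_value({"x": x}), mm_true_rhs(x),
                              atol=1e-8)

    def test_denominator_constant_normalized_to_one(self, mm_library):
        model = fit_candidate(mm_library, mm_library.column("dx"),
                              SolverConfig(threshold=0.9))
        ode = to_explicit_ode(model, "x")
        assert ode.coefficient("1", side="denominator") == 1.0

    def test_no_derivative_terms_not_reducible(self):
        model = CandidateModel(lhs=TermDescriptor((("x", 1),)),
                               terms=[TermDescriptor()],
                               coefficients=np.array([2.0]), threshold=0.1)
        with pytest.raises(NotReducibleError):
            to_explicit_ode(model, "x")

    def test_polynomial_dynamics_give_constant_denominator(self):
        # dx = 2x: lhs dx, rhs 2x -> denominator identically 1
        model = CandidateModel(lhs=TermDescriptor((("dx", 1),)),
                               terms=[TermDescriptor((("x", 1),))],
                               coefficients=np.array([2.0]), threshold=0.1)
        ode = to_explicit_ode(model, "x")
        assert [(t.label, c) for t, c in ode.denominator] == [("1", 1.0)]
        assert ode.coefficient("x") == 2.0

    def test_other_derivative_present_not_reducible(self):
        model = CandidateModel(
            lhs=TermDescriptor((("dx", 1),)),
            terms=[TermDescriptor((("dy", 1),))],
            coefficients=np.array([1.0]), threshold=0.1)
        data = TimeSeriesData(t=np.arange(3.0), X=np.ones((3, 2)),
                              Xdot=np.ones((3, 2)), state_names=("x", "y"))
        with pytest.raises(NotReducibleError):
            to_explicit_ode(model, "x", train_data=data)


class TestSimulateIdentified:
    def _mm_ode(self, mm_library):
        model = fit_candidate(mm_library, mm_library.column("dx*x"),
                              SolverConfig(threshold=0.1))
        return to_explicit_ode(model, "x", train_data=mm_library.source)

    def test_reproduces_true_trajectory(self, mm_library, mm_data):
        ode = self._mm_ode(mm_library)
        t = np.arange(0.0, 10.0 + 1e-9, 0.01)
        sim, ok = simulate_identified([ode], [0.5], t)
        assert ok
        truth = np.interp(t, mm_data.t, mm_data.X[:, 0])
        assert np.max(np.abs(sim.X[:, 0] - truth)) < 1e-4

    def test_fixed_point_stays_put(self, mm_library):
        # j_x (K_m + x) = V_max x  at x = 0.2 for the default parameters
        ode = self._mm_ode(mm_library)
        t = np.arange(0.0, 5.0, 0.01)
        sim, ok = simulate_identified([ode], [0.2], t)
        assert ok
        assert np.max(np.abs(sim.X[:, 0] - 0.2)) < 1e-3

    def test_denominator_crossing_terminates_cleanly(self):
        # dx = 1/(1 - x) from x0=0.5: finite-time blow-up at x -> 1
        ode = RationalODE(state_name="x",
                          numerator=[(TermDescriptor(), 1.0)],
                          denominator=[(TermDescriptor(), 1.0),
                                       (TermDescriptor((("x", 1),)), -1.0)],
                          eps_d=1e-6)
        t = np.arange(0.0, 2.0, 0.001)
        sim, ok = simulate_identified([ode], [0.5], t)
        assert not ok
        assert sim.t[-1] < 2.0 - 0.001
        assert np.all(sim.X[:, 0] <= 1.0)


class TestStructureError:
    def test_exact_match(self):
        s = structure_error({"a", "b", "c"}, {"a", "b", "c"})
        assert (s.added, s.deleted, s.total) == (0, 0, 0)

    def test_set_algebra(self):
        s = structure_error({"a", "b", "d"}, {"a", "b", "c"})
        assert (s.added, s.deleted, s.total) == (1, 1, 2)

    def test_empty_fit(self):
        s = structure_error(set(), {"a", "b", "c"})
        assert (s.added, s.deleted, s.total) == (0, 3, 3)

    def test_vocabulary_mismatch_raises(self, mm_library):
        model = fit_candidate(mm_library, 1, SolverConfig(threshold=0.1))
        with pytest.raises(ValueError, match="vocabulary"):
            structure_error(model, {"not_a_term"})
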