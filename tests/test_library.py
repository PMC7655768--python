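"""Candidate-term enumeration, evaluation and column bookkeeping."""

import numpy as np
import pytest

from sindypi.library import (LibraryError, LibraryMatrix, LibrarySpec,
                             TermDescriptor, TimeSeriesData, enumerate_terms,
                             evaluate_terms, normalize_columns,
                             split_candidate)


def _labels(spec):
    return [t.label for t in enumerate_terms(spec)]


class TestEnumeration:
    def test_single_state_degree_two(self):
        assert _labels(LibrarySpec(state_names=("x",),
                                   derivative_names=())) == ["1", "x", "x^2"]

    def test_two_states_degree_two_count(self):
        # brute enumeration: C(2+2, 2) = 6 monomials up to total degree 2
        labels = _labels(LibrarySpec(state_names=("a", "b"),
                                     derivative_names=()))
        assert len(labels) == 6
        assert len(set(labels)) == 6

    def test_trig_terms_present(self):
        labels = _labels(LibrarySpec(state_names=("phi",),
                                     derivative_names=(), degree=1,
                                     trig_states=("phi",), trig_degree=1))
        assert "sin(phi)" in labels and "cos(phi)" in labels

    def test_constant_first_and_deterministic(self):
        spec = LibrarySpec(state_names=("x", "y"), degree=3,
                           trig_states=("x",))
        a = _labels(spec)
        b = _labels(spec)
        assert a == b
        assert a[0] == "1"

    def test_derivative_products_single_multiplicity(self):
        spec = LibrarySpec(state_names=("x",), degree=2)
        labels = _labels(spec)
        assert "dx*x" in labels and "dx*x^2" in labels
        assert not any(l.startswith("dx^2") for l in labels)

    def test_pythagorean_redundancy_excluded(self):
        spec = LibrarySpec(state_names=("phi",), degree=0,
                           trig_states=("phi",), trig_degree=2)
        labels = _labels(spec)
        assert "cos(phi)^2" in labels
        assert "sin(phi)^2" not in labels
        assert "cos(phi)*sin(phi)" in labels

    def test_invalid_degree_rejected(self):
        with pytest.raises(LibraryError):
            LibrarySpec(state_names=("x",), degree=-1)

    def test_trig_subset_must_be_states(self):
        with pytest.raises(LibraryError):
            LibrarySpec(state_names=("x",), trig_states=("y",))


class TestEvaluation:
    def test_pointwise_closed_forms(self):
        data = TimeSeriesData(t=np.array([0.0, 1.0]),
                              X=np.array([[3.0, 2.0], [0.5, np.pi / 4]]),
                              Xdot=np.array([[0.5, 0.1], [0.2, 0.3]]),
                              state_names=("x", "phi"))
        sq = TermDescriptor((("x", 2),))
        assert sq.evaluate(data.channel)[0] == 9.0
        xxdot = TermDescriptor((("x", 1), ("dx", 1)))
        assert np.isclose(xxdot.evaluate(data.channel)[0], 1.5)
        sc = TermDescriptor((), (("sin", "phi"), ("cos", "phi")))
        assert np.isclose(sc.evaluate(data.channel)[1], 0.5)

    def test_random_terms_match_direct_arithmetic(self):
        rng = np.random.default_rng(42)
        m = 100
        data = TimeSeriesData(t=np.arange(m, dtype=float),
                              X=rng.uniform(0.2, 2.0, (m, 3)),
                              Xdot=rng.normal(size=(m, 3)),
                              state_names=("x1", "x2", "x3"))
        for _ in range(30):
            exps = {f"x{i+1}": int(e)
                    for i, e in enumerate(rng.integers(0, 5, 3))}
            dvar = f"dx{int(rng.integers(1, 4))}"
            exps[dvar] = int(rng.integers(0, 2))
            term = TermDescriptor(tuple(exps.items()))
            expected = np.ones(m)
            for v, e in exps.items():
                expected *= data.channel(v) ** e
            got = term.evaluate(data.channel)
            assert np.allclose(got, expected, rtol=1e-12, atol=0)

    def test_missing_derivative_gives_informative_error(self):
        data = TimeSeriesData(t=np.arange(3.0), X=np.ones((3, 1)),
                              state_names=("x",))
        with pytest.raises(LibraryError, match="derivative"):
            evaluate_terms([TermDescriptor((("dx", 1),))], data)


class TestSplitAndNormalize:
    def _lib(self, m=20, p=5, seed=0):
        rng = np.random.default_rng(seed)
        terms = [TermDescriptor((("x", k),)) for k in range(p)]
        return LibraryMatrix(rng.normal(size=(m, p)), terms)

    def test_split_preserves_order_and_labels(self):
        lib = self._lib()
        lhs, col, reduced = split_candidate(lib, 2)
        assert reduced.p == 4
        assert reduced.labels == [lib.labels[i] for i in (0, 1, 3, 4)]
        assert np.array_equal(col, lib.values[:, 2])

    def test_split_roundtrip_reinsertion(self):
        lib = self._lib()
        _, col, reduced = split_candidate(lib, 2)
        rebuilt = np.insert(reduced.values, 2, col, axis=1)
        assert np.array_equal(rebuilt, lib.values)

    def test_split_out_of_range(self):
        with pytest.raises(IndexError):
            split_candidate(self._lib(), 7)

    def test_degenerate_single_column_split(self):
        lib = LibraryMatrix(np.ones((4, 1)), [TermDescriptor()])
        _, _, reduced = split_candidate(lib, 0)
        assert reduced.p == 0

    def test_normalize_column_norms(self):
        lib = LibraryMatrix(np.array([[3.0, 0.0], [4.0, 0.0]]),
                            [TermDescriptor((("x", 1),)),
                             TermDescriptor((("x", 2),))])
        nl = normalize_columns(lib)
        assert np.isclose(nl.norms[0], 5.0)
        assert np.allclose(nl.values[:, 0], [0.6, 0.8])
        assert nl.zero_columns[1] and nl.norms[1] == 0.0
        assert np.array_equal(nl.values[:, 1], lib.values[:, 1])

    def test_denormalized_solution_matches_unnormalized(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(20, 5)) * rng.uniform(0.1, 50, 5)
        b = rng.normal(size=20)
        lib = LibraryMatrix(A, [TermDescriptor((("x", k),))
                                for k in range(5)])
        nl = normalize_columns(lib)
        xi_n = np.linalg.lstsq(nl.values, b, rcond=None)[0]
        xi_direct = np.linalg.lstsq(A, b, rcond=None)[0]
        assert np.allclose(xi_n / nl.norms, xi_direct, atol=1e-10)


class TestTimeSeriesData:
    def test_rejects_nonincreasing_time(self):
        with pytest.raises(LibraryError):
            TimeSeriesData(t=np.array([0.0, 0.0, 1.0]), X=np.ones((3, 1)))

    def test_rejects_nan(self):
        with pytest.raises(LibraryError):
            TimeSeriesData(t=np.arange(3.0),
                           X=np.array([[1.0], [np.nan], [2.0]]))

    def test_chronological_split_ratio(self):
        data = TimeSeriesData(t=np.arange(100.0), X=np.ones((100, 1)))
        train, valid = data.split(0.8)
        assert train.n_samples == 80 and valid.n_samples == 20
        assert train.t[-1] < valid.t[0]


class TestTermAlgebraProperties:
    """Structural invariants of term descriptors (property-based)."""

    from hypothesis import given, settings, strategies as st

    names = st.sampled_from(["x1", "x2", "dx1", "u1"])
    terms = st.builds(
        lambda factors: TermDescriptor(tuple(factors.items())),
        st.dictionaries(names, st.integers(min_value=0, max_value=4),
                        max_size=4))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=terms, b=terms)
    def test_product_degree_is_additive(self, a, b):
        assert (a * b).degree == a.degree + b.degree

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=terms, b=terms)
    def test_product_commutes_and_label_is_canonical(self, a, b):
        assert (a * b) == (b * a)
        assert (a * b).label == (b * a).label

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=terms)
    def test_evaluation_matches_direct_power_product(self, a):
        rng = np.random.default_rng(0)
        vals = {n: rng.uniform(0.5, 2.0, 7)
                for n in ("x1", "x2", "u1")}
        vals["dx1"] = rng.normal(size=7)
        expected = np.ones(7)
        for v, e in a.factors:
            expected = expected * vals[v] ** e

        def resolve(name):
            if name is None:
                return np.zeros(7)
            return vals[name]

        assert np.allclose(a.evaluate(resolve), expected, rtol=1e-12)
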