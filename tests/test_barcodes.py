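"""Barcode model, bottleneck distances and the toroidality measure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridtorus.barcodes import (Bar, Barcode, BarcodeSet,
                                DegenerateBarcodeError, bar_distance,
                                bottleneck_distance, h1h2_gap,
                                make_reference, normalized_bottleneck,
                                relative_difference, scale_factor,
                                toroidality, ToroidalityScore)
from conftest import brute_bottleneck


def bc(dim, rows):
    return Barcode(dim, rows)


def bset(h1_rows, h2_rows, h0_rows=((0.0, 1.0),)):
    return BarcodeSet(bc(0, h0_rows), bc(1, h1_rows), bc(2, h2_rows))


class TestBarDistance:
    @pytest.mark.parametrize("p,q,expected", [
        ((0, 1), (0, 1), 0.0),
        ((0, 1), (0.2, 1.5), 0.5),
        ((1, 3), (2, 3.4), 1.0),
    ])
    def test_values(self, p, q, expected):
        assert bar_distance(Bar(*p), Bar(*q)) == pytest.approx(expected)
        assert bar_distance(Bar(*q), Bar(*p)) == pytest.approx(expected)

    def test_invalid_bar(self):
        with pytest.raises(ValueError):
            Bar(2.0, 1.0)
        with pytest.raises(ValueError):
            Bar(0.0, np.inf)


class TestBottleneck:
    @pytest.mark.parametrize("P,Q,expected", [
        ([(0, 1)], [(0, 1.5)], 0.5),        # direct match beats diagonals
        ([(0, 2)], [], 1.0),                # only option: diagonal at 1.0
        ([(0, 1), (2, 3)], [(0, 1), (2, 3)], 0.0),
    ])
    def test_examples(self, P, Q, expected):
        assert bottleneck_distance(bc(1, P), bc(1, Q)) == pytest.approx(expected)

    def test_bijection_mode_requires_equal_cardinality(self):
        with pytest.raises(ValueError, match="cardinality mismatch"):
            bottleneck_distance(bc(1, [(0, 1)]), bc(1, [(0, 1), (0, 2)]),
                                allow_diagonal=False)

    def test_bijection_mode_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = rng.integers(1, 6)
            P = np.sort(rng.uniform(0, 3, (n, 2)), axis=1)
            Q = np.sort(rng.uniform(0, 3, (n, 2)), axis=1)
            got = bottleneck_distance(bc(1, P), bc(1, Q),
                                      allow_diagonal=False)
            want = brute_bottleneck(P, Q, allow_diagonal=False)
            assert got == pytest.approx(want, abs=1e-12)

    def test_agrees_with_enumeration_oracle(self):
        """Exact agreement with exhaustive min-max matching on random
        barcode pairs of up to 6 bars."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n1, n2 = rng.integers(0, 7, size=2)
            P = np.sort(rng.uniform(0, 4, (n1, 2)), axis=1)
            Q = np.sort(rng.uniform(0, 4, (n2, 2)), axis=1)
            got = bottleneck_distance(bc(1, P), bc(1, Q))
            want = brute_bottleneck(P, Q)
            assert got == pytest.approx(want, abs=1e-12)


class TestScaleFactor:
    @pytest.mark.parametrize("rows,expected", [
        ([(0, 1), (0, 3)], 2.0),
        ([(0, 1)], 1.0),                     # single bar: its persistence
        ([(0, 1), (0.5, 2), (3, 4)], 3.0),
    ])
    def test_values(self, rows, expected):
        assert scale_factor(bc(1, rows)) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(DegenerateBarcodeError, match="empty"):
            scale_factor(bc(1, []))
        with pytest.raises(DegenerateBarcodeError, match="zero scale"):
            scale_factor(bc(1, [(1, 2), (1, 2)]))


class TestNormalizedBottleneck:
    def test_identity_and_scale_invariant_pair(self):
        P = bc(1, [(0, 1), (0, 3)])
        Q = bc(1, [(0, 2), (0, 6)])  # P scaled by 2: same after rescaling
        assert normalized_bottleneck(P, P) == 0.0
        assert normalized_bottleneck(P, Q) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 5), st.floats(0.01, 5)),
                    min_size=2, max_size=5),
           st.lists(st.tuples(st.floats(0, 5), st.floats(0.01, 5)),
                    min_size=2, max_size=5),
           st.floats(0.1, 50))
    def test_symmetric_bounded_scale_invariant(self, rows_p, rows_q, scale):
        P = bc(1, [(b, b + L) for b, L in rows_p])
        Q = bc(1, [(b, b + L) for b, L in rows_q])
        try:
            d_pq = normalized_bottleneck(P, Q)
        except DegenerateBarcodeError:
            return
        assert 0.0 <= d_pq <= 1.0
        assert normalized_bottleneck(Q, P) == pytest.approx(d_pq, abs=1e-9)
        P2 = bc(1, P.array * scale)
        assert normalized_bottleneck(P2, Q) == pytest.approx(d_pq, rel=1e-6,
                                                             abs=1e-9)


class TestMakeReference:
    def test_data_mode_example(self):
        s = bset([(0.1, 0.9), (0.2, 0.8), (0.3, 0.5), (0.4, 0.45)],
                 [(0.5, 0.7)])
        ref = make_reference(s, "data")
        # min H1 length 0.05 applied to the non-retained bars
        assert np.allclose(ref.h1._sorted(),
                           [(0.1, 0.9), (0.2, 0.8), (0.3, 0.35), (0.4, 0.45)])
        assert np.allclose(ref.h2.array, [(0.5, 0.7)])

    def test_self_mode_stretches_second_bar(self):
        s = bset([(0.1, 0.9), (0.2, 0.4)], [(0.5, 0.7)])
        ref = make_reference(s, "self")
        assert np.allclose(ref.h1._sorted(), [(0.1, 0.9), (0.2, 1.0)])

    @pytest.mark.parametrize("mode", ["data", "self"])
    def test_idempotent(self, mode):
        rng = np.random.default_rng(3)
        arr1 = np.sort(rng.uniform(0, 2, (6, 2)), axis=1)
        arr2 = np.sort(rng.uniform(0, 2, (4, 2)), axis=1)
        ref1 = make_reference(bset(arr1, arr2), mode)
        ref2 = make_reference(ref1, mode)
        assert ref1.h1 == ref2.h1 and ref1.h2 == ref2.h2

    def test_insufficient_bars(self):
        with pytest.raises(DegenerateBarcodeError, match="insufficient"):
            make_reference(bset([(0, 1)], [(0, 1)]), "data")


class TestToroidality:
    def test_reference_scores_perfectly_against_itself(self):
        s = bset([(0.1, 0.9), (0.2, 0.8), (0.3, 0.35)], [(0.5, 0.7), (0.6, 0.62)])
        ref = make_reference(s, "data")
        score = toroidality(ref, ref)
        assert score.as_tuple() == (1.0, 1.0)

    def test_noise_on_endpoints_degrades_score_monotonically(self):
        """Averaged over seeds, Gamma against the clean data-mode reference
        is non-increasing as uniform endpoint noise grows."""
        rng = np.random.default_rng(11)
        base = bset([(0.1, 2.0), (0.15, 1.9)] +
                    [(b, b + 0.1) for b in rng.uniform(0.1, 2, 10)],
                    [(0.8, 1.6)] + [(b, b + 0.05) for b in rng.uniform(0.5, 1.5, 5)])
        ref = make_reference(base, "data")
        levels = [0.0, 0.2, 0.6]
        means = []
        for lv in levels:
            g = []
            for s in range(10):
                r2 = np.random.default_rng(100 + s)
                arr1 = base.h1.array + r2.uniform(-lv, lv, base.h1.array.shape)
                arr2 = base.h2.array + r2.uniform(-lv, lv, base.h2.array.shape)
                noisy = bset(np.sort(arr1, axis=1), np.sort(arr2, axis=1))
                sc = toroidality(noisy, ref)
                g.append(min(sc.gamma1, sc.gamma2))
            means.append(np.mean(g))
        assert means[0] >= means[1] - 1e-9 >= means[2] - 2e-9

    def test_degenerate_flagged_not_zero(self):
        s = bset([(0.1, 0.9), (0.2, 0.8)], [(0.5, 0.7)])
        bad = BarcodeSet(s.h0, Barcode(1, []), s.h2)
        score = toroidality(bad, make_reference(s, "data"))
        assert score.undefined and np.isnan(score.gamma1)


class TestGapAndRelativeDifference:
    def test_gap_values(self):
        s = bset([(0.2, 0.8), (0.25, 0.7)], [(0.5, 0.7)])
        assert h1h2_gap(s) == pytest.approx(0.3)
        s2 = bset([(0.2, 0.5), (0.25, 0.45)], [(0.5, 0.7)])
        assert h1h2_gap(s2) == pytest.approx(0.0)

    def test_relative_difference(self):
        a = ToroidalityScore(0.8, 0.8)
        b = ToroidalityScore(0.4, 0.4)
        assert relative_difference(a, b) == pytest.approx((1 / 3, 1 / 3))
        assert relative_difference(a, a) == (0.0, 0.0)
        z = ToroidalityScore(0.0, 0.0)
        assert relative_difference(a, z) == (1.0, 1.0)
        assert np.isnan(relative_difference(z, z)[0])
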