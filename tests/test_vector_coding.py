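"""Coefficient-of-correspondence contracts, including equivalence with a
naive double-loop oracle."""

import numpy as np
import pytest

from cutcoord.vector_coding import (
    Coupling,
    CouplingCurveSet,
    CoordinationVariabilityCurve,
    coefficient_of_correspondence,
    curve_set_from_frame,
    curves_to_frame,
    frame_vectors,
    summarize_variability,
)


def naive_coc(prox: np.ndarray, dist: np.ndarray):
    """Straightforward double-loop implementation used as the oracle."""
    k, n = prox.shape
    a = np.empty(n - 1)
    m = np.empty(n - 1)
    for i in range(n - 1):
        vecs = []
        for j in range(k):
            vecs.append((prox[j, i + 1] - prox[j, i],
                         dist[j, i + 1] - dist[j, i]))
        lengths = [np.hypot(dx, dy) for dx, dy in vecs]
        nonzero = [(dx, dy, l) for (dx, dy), l in zip(vecs, lengths) if l > 0]
        if not nonzero:
            a[i] = 1.0
            m[i] = 1.0
            continue
        cos_sum = sum(dx / l for dx, dy, l in nonzero) / len(nonzero)
        sin_sum = sum(dy / l for dx, dy, l in nonzero) / len(nonzero)
        a[i] = np.hypot(cos_sum, sin_sum)
        mean_l = np.mean(lengths)
        sd_l = np.std(lengths)
        m[i] = min(max(1.0 - sd_l / mean_l, 0.0), 1.0)
    return a, m, a * m


def make_set(prox, dist):
    return CouplingCurveSet(np.asarray(prox, float), np.asarray(dist, float))


class TestFrameVectors:
    def test_constant_curves_give_zero_vectors(self):
        s = make_set(np.full((3, 101), 2.0), np.full((3, 101), -1.0))
        assert np.all(frame_vectors(s) == 0.0)

    def test_linear_curves(self):
        idx = np.arange(101, dtype=float)
        s = make_set(np.tile(idx, (2, 1)), np.tile(2 * idx, (2, 1)))
        v = frame_vectors(s)
        np.testing.assert_allclose(v[..., 0], 1.0)
        np.testing.assert_allclose(v[..., 1], 2.0)

    def test_matches_brute_force_differencing(self, rng):
        prox = rng.normal(size=(3, 101))
        dist = rng.normal(size=(3, 101))
        v = frame_vectors(make_set(prox, dist))
        for j in range(3):
            for i in range(100):
                assert v[j, i, 0] == prox[j, i + 1] - prox[j, i]
                assert v[j, i, 1] == dist[j, i + 1] - dist[j, i]

    def test_non_finite_rejected_with_location(self):
        prox = np.zeros((2, 101))
        prox[1, 40] = np.nan
        with pytest.raises(ValueError, match="cycle 1, frame 40"):
            frame_vectors(make_set(prox, np.zeros((2, 101))))


class TestCoefficientOfCorrespondence:
    def test_identical_cycles_give_unity(self, rng):
        cycle = np.cumsum(rng.normal(size=101))
        s = make_set(np.tile(cycle, (4, 1)), np.tile(cycle[::-1], (4, 1)))
        c = coefficient_of_correspondence(s)
        np.testing.assert_allclose(c.a, 1.0, atol=1e-12)
        np.testing.assert_allclose(c.m, 1.0, atol=1e-12)
        np.testing.assert_allclose(c.r, 1.0, atol=1e-12)

    def test_antipodal_directions_cancel(self):
        # cycle 1 moves +1 in proximal each frame, cycle 2 moves -1
        prox = np.stack([np.arange(101.0), -np.arange(101.0)])
        dist = np.zeros((2, 101))
        c = coefficient_of_correspondence(make_set(prox, dist))
        np.testing.assert_allclose(c.a, 0.0, atol=1e-12)
        np.testing.assert_allclose(c.r, 0.0, atol=1e-12)

    def test_orthogonal_unit_vectors(self):
        # cycle 1: (1,0) steps; cycle 2: (0,1) steps
        prox = np.stack([np.arange(101.0), np.zeros(101)])
        dist = np.stack([np.zeros(101), np.arange(101.0)])
        c = coefficient_of_correspondence(make_set(prox, dist))
        np.testing.assert_allclose(c.a, np.hypot(0.5, 0.5), atol=1e-12)
        np.testing.assert_allclose(c.m, 1.0, atol=1e-12)
        np.testing.assert_allclose(c.r, 0.70711, atol=5e-6)

    def test_all_zero_interval_convention(self):
        prox = np.tile(np.concatenate([np.arange(51.0), np.full(50, 50.0)]),
                       (3, 1))
        c = coefficient_of_correspondence(make_set(prox, prox))
        np.testing.assert_allclose(c.r[50:], 1.0, atol=1e-12)

    def test_fewer_than_two_cycles_rejected(self):
        with pytest.raises(ValueError, match="k >= 2"):
            make_set(np.zeros((1, 101)), np.zeros((1, 101)))

    def test_components_in_unit_interval(self, rng):
        s = make_set(rng.normal(size=(5, 101)), rng.normal(size=(5, 101)))
        c = coefficient_of_correspondence(s)
        for arr in (c.a, c.m, c.r):
            assert np.all(arr >= 0.0) and np.all(arr <= 1.0)

    def test_cycle_permutation_invariance(self, rng):
        prox = rng.normal(size=(5, 101))
        dist = rng.normal(size=(5, 101))
        c1 = coefficient_of_correspondence(make_set(prox, dist))
        perm = rng.permutation(5)
        c2 = coefficient_of_correspondence(make_set(prox[perm], dist[perm]))
        np.testing.assert_allclose(c1.r, c2.r, atol=1e-12)

    def test_scale_and_offset_invariance(self, rng):
        prox = rng.normal(size=(4, 101))
        dist = rng.normal(size=(4, 101))
        c1 = coefficient_of_correspondence(make_set(prox, dist))
        c2 = coefficient_of_correspondence(
            make_set(3.7 * prox + 11.0, 3.7 * dist - 5.0)
        )
        np.testing.assert_allclose(c1.a, c2.a, atol=1e-12)
        np.testing.assert_allclose(c1.m, c2.m, atol=1e-12)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(987)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            prox = rng.normal(scale=rng.uniform(0.1, 30), size=(k, 101))
            dist = rng.normal(scale=rng.uniform(0.1, 30), size=(k, 101))
            c = coefficient_of_correspondence(make_set(prox, dist))
            a, m, r = naive_coc(prox, dist)
            np.testing.assert_allclose(c.a, a, atol=1e-12)
            np.testing.assert_allclose(c.m, m, atol=1e-12)
            np.testing.assert_allclose(c.r, r, atol=1e-12)


class TestSummarizeVariability:
    def _curve(self, r):
        r = np.asarray(r, float)
        return CoordinationVariabilityCurve(r=r, a=np.sqrt(r), m=np.sqrt(r))

    def test_constant_curve(self):
        assert summarize_variability(self._curve(np.full(100, 0.7))) == \
            (pytest.approx(0.7), pytest.approx(0.7))

    def test_ramp_curve(self):
        mean, mx = summarize_variability(self._curve(np.arange(100) / 100))
        assert mean == pytest.approx(0.495)
        assert mx == pytest.approx(0.99)

    def test_window_restriction(self):
        r = np.concatenate([np.zeros(50), np.ones(50)])
        mean, mx = summarize_variability(self._curve(r), window=(0.0, 50.0))
        assert mean == pytest.approx(0.0)
        with pytest.raises(ValueError):
            summarize_variability(self._curve(r), window=(70.0, 20.0))


def test_csv_round_trip(rng):
    prox = rng.normal(size=(3, 101))
    dist = rng.normal(size=(3, 101))
    rows = []
    for j in range(3):
        for f in range(101):
            rows.append({"cycle": j, "frame": f,
                         "proximal": prox[j, f], "distal": dist[j, f]})
    import pandas as pd

    df = pd.DataFrame(rows)
    # a non-standard coupling needs the explicit opt-in flag
    with pytest.raises(ValueError, match="standard"):
        curve_set_from_frame(df, coupling=Coupling("X", "a", "b"))
    s = curve_set_from_frame(df, coupling=Coupling("X", "a", "b"),
                             allow_custom=True)
    c = coefficient_of_correspondence(s)
    a, m, r = naive_coc(prox, dist)
    np.testing.assert_allclose(c.r, r, atol=1e-12)
    out = curves_to_frame(c)
    assert list(out.columns) == ["interval", "a", "m", "r"]
    assert len(out) == 100
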