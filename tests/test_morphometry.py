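"""2D and inferred-3D trace morphometrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corset.errors import InvalidTraceError
from corset.morphometry import (
    MitoTrace,
    circularity_2d,
    cristae_fraction_2d,
    cristae_fraction_3d,
    estimate_diameter,
    measure_trace,
    stadium_outline_closed_forms,
)
from corset.synth import generate_stadium_trace


def regular_polygon(n, R=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return R * np.column_stack([np.cos(th), np.sin(th)])


class TestCircularity:
    def test_fine_circle_is_one(self):
        m = circularity_2d(regular_polygon(10_000, 300.0))
        assert m["circularity"] == pytest.approx(1.0, abs=1e-5)

    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        m = circularity_2d(square)
        assert m["area_2d"] == pytest.approx(1.0)
        assert m["perimeter"] == pytest.approx(4.0)
        assert m["circularity"] == pytest.approx(np.pi / 4)

    def test_stadium_closed_forms(self):
        """L = 500 nm straight section, R = 125 nm caps."""
        cf = stadium_outline_closed_forms(500.0, 125.0)
        assert cf["area"] == pytest.approx(174_087, rel=1e-3)
        assert cf["perimeter"] == pytest.approx(1_785.4, rel=1e-3)
        assert cf["circularity"] == pytest.approx(0.686, abs=1e-3)
        tr = generate_stadium_trace(500.0, 125.0)
        m = circularity_2d(tr.outline)
        assert m["circularity"] == pytest.approx(cf["circularity"], abs=1e-3)

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(InvalidTraceError):
            circularity_2d(bowtie)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(InvalidTraceError):
            circularity_2d(np.array([[0, 0], [1, 1]], dtype=float))

    @given(
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.05, 50.0),
        dx=st.floats(-1e4, 1e4),
        dy=st.floats(-1e4, 1e4),
    )
    @settings(max_examples=30, deadline=None)
    def test_rigid_motion_and_scale_invariance(self, angle, scale, dx, dy):
        base = generate_stadium_trace(700.0, 150.0).outline
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = scale * base @ rot.T + [dx, dy]
        c0 = circularity_2d(base)["circularity"]
        c1 = circularity_2d(moved)["circularity"]
        assert c1 == pytest.approx(c0, rel=1e-9)

    def test_regular_ngon_convergence(self):
        """Polygon area/perimeter approach the circle as O(1/n²)."""
        errs = [abs(circularity_2d(regular_polygon(n))["circularity"] - 1.0)
                for n in (64, 128, 256)]
        assert errs[1] <= errs[0] / 3.5
        assert errs[2] <= errs[1] / 3.5


class TestEstimateDiameter:
    def test_exact_stadium(self):
        tr = generate_stadium_trace(500.0, 125.0)
        d, fallback = estimate_diameter(tr.outline)
        assert not fallback
        assert d == pytest.approx(250.0, rel=0.01)

    def test_circle_fallback(self):
        d, fallback = estimate_diameter(regular_polygon(512, 300.0))
        assert fallback
        assert d == pytest.approx(600.0, rel=0.01)

    def test_jittered_stadium_within_5_percent(self):
        """Robust to 2% vertex jitter across 100 seeds."""
        estimates = []
        for seed in range(100):
            tr = generate_stadium_trace(500.0, 125.0, jitter=0.02, seed=seed)
            d, _ = estimate_diameter(tr.outline)
            estimates.append(d)
        assert np.all(np.abs(np.array(estimates) - 250.0) / 250.0 < 0.05)


class TestCristaeFractions:
    def test_2d_formula(self):
        """P = 2000 nm with three 200 nm cristae: doubled lengths give 37.5%."""
        # stadium with perimeter 2000: 2L + 2πR = 2000, R = 125
        L = (2000 - 2 * np.pi * 125.0) / 2
        tr = generate_stadium_trace(L, 125.0)
        cristae = [np.array([[x, -100.0], [x, 100.0]]) for x in (-200, 0, 200)]
        trace = MitoTrace(outline=tr.outline, cristae=cristae)
        expected = 100 * 1200 / (trace.polygon.exterior.length + 1200)
        assert cristae_fraction_2d(trace) == pytest.approx(expected, rel=1e-9)
        assert cristae_fraction_2d(trace) == pytest.approx(37.5, abs=0.1)

    def test_no_cristae_zero(self):
        tr = generate_stadium_trace(500.0, 125.0)
        assert cristae_fraction_2d(tr) == 0.0

    def test_single_crista_half_perimeter(self):
        tr = generate_stadium_trace(800.0, 125.0)
        P = tr.polygon.exterior.length
        trace = MitoTrace(
            outline=tr.outline,
            cristae=[np.array([[-P / 4, 0.0], [P / 4, 0.0]])],
        )
        assert cristae_fraction_2d(trace) == pytest.approx(50.0, rel=1e-9)

    def test_3d_transformation(self):
        """Cylinder-with-caps boundary πRP plus two-faced crista disks."""
        L = (2000 - 2 * np.pi * 125.0) / 2
        tr = generate_stadium_trace(L, 125.0)
        cristae = [np.array([[x, -100.0], [x, 100.0]]) for x in (-200, 0, 200)]
        trace = MitoTrace(outline=tr.outline, cristae=cristae)
        res = cristae_fraction_3d(trace)
        P = trace.polygon.exterior.length
        assert res["s_boundary"] == pytest.approx(np.pi * 125.0 * P, rel=0.01)
        assert res["s_cristae"] == pytest.approx(3 * 2 * np.pi * 100.0**2,
                                                 rel=1e-9)
        assert res["percent"] == pytest.approx(19.4, abs=0.5)

    def test_oversized_crista_flagged_not_dropped(self):
        tr = generate_stadium_trace(500.0, 125.0)
        big = np.array([[-250.0, 0.0], [250.0, 0.0]])  # 500 nm > 1.5×250 nm
        trace = MitoTrace(outline=tr.outline, cristae=[big])
        res = cristae_fraction_3d(trace)
        assert res["flagged_cristae"] == [0]
        assert res["s_cristae"] > 0

    @given(factor=st.floats(1.01, 1.8))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_crista_length(self, factor):
        tr = generate_stadium_trace(600.0, 140.0)
        short = MitoTrace(outline=tr.outline,
                          cristae=[np.array([[0, -80.0], [0, 80.0]])])
        long = MitoTrace(outline=tr.outline,
                         cristae=[np.array([[0, -80.0 * factor],
                                            [0, 80.0 * factor]])])
        assert cristae_fraction_2d(long) > cristae_fraction_2d(short)
        assert (cristae_fraction_3d(long)["percent"]
                > cristae_fraction_3d(short)["percent"])


class TestMeasureTrace:
    def test_full_record(self):
        tr = generate_stadium_trace(500.0, 125.0, n_cristae=3, crista_span=0.8)
        m = measure_trace(tr)
        assert m.n_cristae == 3
        assert m.has_cristae
        assert 0 < m.circularity <= 1 + 1e-6
        assert 0 <= m.cristae_frac_2d <= 100
        assert 0 <= m.cristae_frac_3d <= 100
        assert m.cristae_lengths == pytest.approx([0.8 * 250.0] * 3)
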