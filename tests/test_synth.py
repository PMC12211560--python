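"""Synthetic tracing generator: cohorts, time series, rasters."""

import numpy as np
import pytest

from corset.errors import CapacityError, InvalidParameterError
from corset.morphometry import circularity_2d, cristae_fraction_2d, \
    polyline_length
from corset.synth import (
    CohortSpec,
    generate_cohort,
    generate_stadium_trace,
    generate_timeseries,
    generate_two_group_cohort,
    rasterize_trace,
)


def total_imm_length(trace):
    P = circularity_2d(trace.outline)["perimeter"]
    return P + 2 * sum(polyline_length(c) for c in trace.cristae)


class TestStadiumTrace:
    def test_zero_axis_is_circle(self):
        tr = generate_stadium_trace(0.0, 250.0)
        assert circularity_2d(tr.outline)["circularity"] == pytest.approx(
            1.0, abs=1e-3
        )

    def test_matches_closed_form(self):
        tr = generate_stadium_trace(500.0, 125.0, jitter=0.0)
        assert circularity_2d(tr.outline)["circularity"] == pytest.approx(
            0.686, abs=1e-3
        )

    def test_crista_geometry_plugs_into_fraction(self):
        tr = generate_stadium_trace(500.0, 125.0, n_cristae=3, crista_span=0.8)
        P = circularity_2d(tr.outline)["perimeter"]
        expected = 100 * (2 * 3 * 0.8 * 250) / (P + 2 * 3 * 0.8 * 250)
        assert cristae_fraction_2d(tr) == pytest.approx(expected, rel=1e-6)

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_stadium_trace(200.0, 125.0, n_cristae=10)

    def test_deterministic_given_seed(self):
        a = generate_stadium_trace(500.0, 125.0, jitter=0.03, seed=9)
        b = generate_stadium_trace(500.0, 125.0, jitter=0.03, seed=9)
        assert np.array_equal(a.outline, b.outline)

    def test_truth_recovery_without_jitter(self):
        """Measured crista lengths equal the generated ones exactly."""
        tr = generate_stadium_trace(800.0, 150.0, n_cristae=4, crista_span=0.6)
        lengths = [polyline_length(c) for c in tr.cristae]
        assert lengths == pytest.approx([0.6 * 300.0] * 4)


class TestCohort:
    def test_deterministic_coupling_is_exact(self):
        traces, _ = generate_cohort(
            CohortSpec(n=50, coupling_r=-1.0, noise_sd=0.0,
                       outline_jitter=0.0, seed=3)
        )
        f = [cristae_fraction_2d(t) for t in traces]
        c = [circularity_2d(t.outline)["circularity"] for t in traces]
        assert np.corrcoef(f, c)[0, 1] == pytest.approx(-1.0, abs=1e-6)

    def test_target_coupling_recovered(self):
        traces, truth = generate_cohort(CohortSpec(n=100, coupling_r=-0.6,
                                                   seed=42))
        assert truth.attrs["achieved_r"] == pytest.approx(-0.6, abs=0.15)
        assert len(traces) == 100
        assert len(truth) == 100

    def test_null_coupling_small(self):
        rs = []
        for seed in range(40):
            _, truth = generate_cohort(CohortSpec(n=100, coupling_r=0.0,
                                                  seed=seed))
            rs.append(truth.attrs["achieved_r"])
        assert abs(np.mean(rs)) < 0.06

    def test_invalid_spec(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(n=2)
        with pytest.raises(InvalidParameterError):
            CohortSpec(coupling_r=-1.5)

    def test_reproducible_by_seed(self):
        a, _ = generate_cohort(CohortSpec(n=10, seed=7))
        b, _ = generate_cohort(CohortSpec(n=10, seed=7))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.outline, tb.outline)
            assert all(np.array_equal(x, y)
                       for x, y in zip(ta.cristae, tb.cristae))


class TestTimeseries:
    def test_conservation_of_total_imm_length(self):
        frames = generate_timeseries(n_frames=8, conserve_imm_length=True)
        totals = [total_imm_length(f) for f in frames]
        assert (max(totals) - min(totals)) / max(totals) < 1e-3

    def test_full_retraction_endpoint(self):
        frames = generate_timeseries(n_frames=6, conserve_imm_length=True)
        last = frames[-1]
        assert cristae_fraction_2d(last) == 0.0
        assert circularity_2d(last.outline)["circularity"] >= 0.95

    def test_monotone_fraction(self):
        frames = generate_timeseries(n_frames=7)
        fracs = [cristae_fraction_2d(f) for f in frames]
        assert all(b <= a + 1e-9 for a, b in zip(fracs, fracs[1:]))

    def test_schedule_must_be_non_increasing(self):
        with pytest.raises(InvalidParameterError):
            generate_timeseries(retraction_schedule=[1.0, 0.5, 0.8])

    def test_timestamps_attached(self):
        frames = generate_timeseries(n_frames=4, frame_interval=30.0)
        assert [f.timestamp for f in frames] == [0.0, 30.0, 60.0, 90.0]


class TestTwoGroupCohort:
    def test_labels_and_shift(self):
        ctrl = CohortSpec(n=20, seed=1)
        traces, truth = generate_two_group_cohort(ctrl)
        labels = {t.group_label for t in traces}
        assert labels == {"control", "perturbed"}
        mean_len = truth.groupby("group_label")["axis_length"].mean()
        assert mean_len["perturbed"] < mean_len["control"]

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_two_group_cohort(CohortSpec(n=0, seed=1))


class TestRasterize:
    def test_dimensions_and_ridges(self):
        tr = generate_stadium_trace(500.0, 125.0, n_cristae=2, crista_span=0.8)
        res = rasterize_trace(tr, pixel_size=25.0)
        img = res["image"]
        span = tr.outline.max(axis=0) - tr.outline.min(axis=0)
        expected = np.ceil(span / 25.0).astype(int) + 1 + 4
        assert img.shape == (expected[1], expected[0])
        # ridge pixels sit on the input polylines (within one pixel)
        rows, cols = np.nonzero(img)
        pts = np.column_stack([cols, rows]) * 25.0 + res["origin"]
        from shapely.geometry import LineString, Point

        boundary = LineString(np.vstack([tr.outline, tr.outline[:1]]))
        lines = [boundary] + [LineString(c) for c in tr.cristae]
        dist = np.array(
            [min(ln.distance(Point(p)) for ln in lines) for p in pts]
        )
        assert dist.max() <= 25.0 * 1.5

    def test_retrace_roundtrip_recovers_circularity(self):
        """Filling the noiseless outline raster re-measures circularity to 2%."""
        from scipy import ndimage
        from skimage import measure

        tr = generate_stadium_trace(600.0, 150.0)
        bare = rasterize_trace(
            type(tr)(outline=tr.outline, cristae=[], id="o"), pixel_size=15.0
        )
        filled = ndimage.binary_fill_holes(bare["image"] > 0)
        contour = max(measure.find_contours(filled.astype(float), 0.5),
                      key=len)
        poly = contour[:, ::-1] * 15.0  # (row, col) -> (x, y) in nm
        c_in = circularity_2d(tr.outline)["circularity"]
        c_out = circularity_2d(poly[::3])["circularity"]
        assert c_out == pytest.approx(c_in, rel=0.02)
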