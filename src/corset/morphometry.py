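"""2D and inferred-3D morphometrics of traced mitochondria.

A tracing consists of the closed outline of a mitochondrion plus open
polylines marking individual cristae, all in nm.  From these the module
computes the shape descriptors used throughout the analysis:

- 2D circularity 4π·area/perimeter² (1 for a circle);
- the cristae length fraction of the inner membrane,
  [cristae/IMM]% = 100·(2Σl)/(P + 2Σl), where each traced crista length
  is doubled because a crista comprises two membrane layers;
- an inferred 3D transformation treating the mitochondrion as a cylinder
  with hemispherical caps of radius R: the boundary-membrane surface is
  S_boundary = π·R·P (each axial ring of width L1 has 3D area 2πR·L1 and
  contributes 2·L1 to the traced perimeter), and each crista is a
  two-faced flat disk of diameter equal to its traced length l,
  S_crista = 2·π·(l/2)².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

from .errors import InvalidParameterError, InvalidTraceError


@dataclass
class MitoTrace:
    """One mitochondrion tracing: outline polygon + cristae polylines (nm)."""

    outline: np.ndarray                 # (n, 2) closed polygon vertices
    cristae: list = field(default_factory=list)  # list of (m_i, 2) polylines
    id: str = ""
    timestamp: float | None = None      # seconds, for time series
    pixel_size: float | None = None     # nm, provenance only
    group_label: str | None = None
    extras: dict = field(default_factory=dict)  # unknown file fields, preserved

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        self.cristae = [np.asarray(c, dtype=float) for c in self.cristae]
        validate_outline(self.outline, record=self.id)
        for j, c in enumerate(self.cristae):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
                raise InvalidTraceError(
                    f"trace {self.id!r}: crista {j} needs >= 2 vertices"
                )
            if polyline_length(c) <= 0:
                raise InvalidTraceError(
                    f"trace {self.id!r}: crista {j} has zero length"
                )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.outline)


@dataclass
class MitoMeasurement:
    """Derived morphometrics of one tracing."""

    id: str
    area_2d: float            # nm²
    perimeter: float          # nm
    circularity: float
    diameter: float           # 2R, nm
    diameter_fallback: bool   # True if caliper fallback was used
    cristae_lengths: list     # nm, as traced (not doubled)
    cristae_frac_2d: float    # percent
    s_boundary: float         # nm²
    s_cristae: float          # nm²
    cristae_frac_3d: float    # percent
    n_cristae: int
    flagged_cristae: list     # indices with length > 1.5 × diameter
    has_cristae: bool
    timestamp: float | None = None
    group_label: str | None = None
    size_class: str | None = None   # small | large, assigned by the pipeline


def validate_outline(outline: np.ndarray, record: str = "") -> None:
    """Check the outline is a simple polygon with ≥3 non-collinear vertices."""
    outline = np.asarray(outline, dtype=float)
    if outline.ndim != 2 or outline.shape[1] != 2 or outline.shape[0] < 3:
        raise InvalidTraceError(
            f"trace {record!r}: outline needs at least 3 (x, y) vertices"
        )
    poly = Polygon(outline)
    if poly.area <= 0:
        raise InvalidTraceError(f"trace {record!r}: outline vertices are collinear")
    if not poly.is_valid or not poly.is_simple:
        raise InvalidTraceError(f"trace {record!r}: outline self-intersects")


def polyline_length(vertices: np.ndarray) -> float:
    """Length of an open polyline, nm."""
    v = np.asarray(vertices, dtype=float)
    return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))


def circularity_2d(outline: np.ndarray) -> dict:
    """Shoelace area, closed perimeter, and circularity 4π·area/perimeter².

    Discretized near-circles may exceed 1 by a small amount; values are
    stored as computed (clipping, if any, happens only in reports).
    """
    validate_outline(outline)
    poly = Polygon(outline)
    area = poly.area
    perimeter = poly.exterior.length
    return {
        "area_2d": float(area),
        "perimeter": float(perimeter),
        "circularity": float(4.0 * np.pi * area / perimeter**2),
    }


def estimate_diameter(outline: np.ndarray, n_chords: int = 15) -> tuple[float, bool]:
    """Width 2R of an outline, as chords perpendicular to the principal axis.

    The principal axis comes from the second moments of the outline
    vertices; the diameter is the median chord length across the middle
    80% of the axial extent.  Near-circular outlines (principal-moment
    axis ratio < 1.05) fall back to the mean caliper width, which by
    Cauchy's formula equals convex-hull perimeter / π; the fallback is
    flagged in the second return value.
    """
    validate_outline(outline)
    poly = Polygon(outline)
    v = np.asarray(outline, dtype=float)
    centred = v - v.mean(axis=0)
    cov = np.cov(centred.T)
    evals, evecs = np.linalg.eigh(cov)
    axis_ratio = np.sqrt(evals[1] / max(evals[0], 1e-30))
    if axis_ratio < 1.05:
        return float(poly.convex_hull.exterior.length / np.pi), True
    major = evecs[:, 1]
    u = centred @ major                      # axial coordinate
    lo, hi = np.quantile(u, [0.10, 0.90])    # middle 80% of the extent
    minor = evecs[:, 0]
    span = 2.0 * float(np.sqrt(evals[0])) * 6.0 + 1.0
    centre = v.mean(axis=0)
    chords = []
    for ui in np.linspace(lo, hi, n_chords):
        p0 = centre + ui * major - span * minor
        p1 = centre + ui * major + span * minor
        seg = poly.intersection(LineString([p0, p1]))
        if not seg.is_empty:
            chords.append(seg.length)
    if not chords:
        return float(poly.convex_hull.exterior.length / np.pi), True
    return float(np.median(chords)), False


def cristae_fraction_2d(trace: MitoTrace) -> float:
    """[cristae/IMM]% in 2D: 100·(2Σl)/(P + 2Σl); 0 with no cristae."""
    P = circularity_2d(trace.outline)["perimeter"]
    total = 2.0 * sum(polyline_length(c) for c in trace.cristae)
    return 100.0 * total / (P + total)


def cristae_fraction_3d(trace: MitoTrace) -> dict:
    """Inferred 3D cristae surface fraction.

    Returns S_boundary = π·R·P, the summed two-faced disk areas
    S_cristae = Σ 2π(l/2)², and percent = 100·S_cristae/(S_cristae +
    S_boundary).  Cristae longer than 1.5× the local width are flagged
    (likely tracing errors) but still counted.
    """
    meas = circularity_2d(trace.outline)
    diameter, fallback = estimate_diameter(trace.outline)
    R = diameter / 2.0
    s_boundary = np.pi * R * meas["perimeter"]
    s_cristae = 0.0
    flagged = []
    for j, c in enumerate(trace.cristae):
        length = polyline_length(c)
        s_cristae += 2.0 * np.pi * (length / 2.0) ** 2
        if length > 1.5 * _local_width(trace, c, diameter):
            flagged.append(j)
    percent = 100.0 * s_cristae / (s_cristae + s_boundary) if s_cristae else 0.0
    return {
        "s_boundary": float(s_boundary),
        "s_cristae": float(s_cristae),
        "percent": float(percent),
        "diameter": float(diameter),
        "diameter_fallback": fallback,
        "flagged_cristae": flagged,
    }


def _local_width(trace: MitoTrace, crista: np.ndarray, default: float) -> float:
    """Transverse outline width at the crista midpoint.

    Measured perpendicular to the outline's principal axis; falls back to
    the global diameter estimate for degenerate geometry.
    """
    v = trace.outline - trace.outline.mean(axis=0)
    _, evecs = np.linalg.eigh(np.cov(v.T))
    minor = evecs[:, 0]  # perpendicular to the principal (major) axis
    mid = crista.mean(axis=0)
    span = default * 4.0 + 1.0
    seg = Polygon(trace.outline).intersection(
        LineString([mid - span * minor, mid + span * minor])
    )
    return float(seg.length) if not seg.is_empty else default


def measure_trace(trace: MitoTrace) -> MitoMeasurement:
    """Full morphometric record for one tracing."""
    meas = circularity_2d(trace.outline)
    three_d = cristae_fraction_3d(trace)
    lengths = [polyline_length(c) for c in trace.cristae]
    return MitoMeasurement(
        id=trace.id,
        area_2d=meas["area_2d"],
        perimeter=meas["perimeter"],
        circularity=meas["circularity"],
        diameter=three_d["diameter"],
        diameter_fallback=three_d["diameter_fallback"],
        cristae_lengths=lengths,
        cristae_frac_2d=cristae_fraction_2d(trace),
        s_boundary=three_d["s_boundary"],
        s_cristae=three_d["s_cristae"],
        cristae_frac_3d=three_d["percent"],
        n_cristae=len(lengths),
        flagged_cristae=three_d["flagged_cristae"],
        has_cristae=bool(lengths),
        timestamp=trace.timestamp,
        group_label=trace.group_label,
    )


def stadium_outline_closed_forms(straight_length: float, radius: float) -> dict:
    """Closed-form area/perimeter/circularity of an ideal stadium.

    area = 2·R·L + πR², perimeter = 2L + 2πR.  Used as an oracle for
    generated outlines and as a reference point for trace validation.
    """
    if radius <= 0 or straight_length < 0:
        raise InvalidParameterError("stadium needs radius > 0, length >= 0")
    area = 2.0 * radius * straight_length + np.pi * radius**2
    perimeter = 2.0 * straight_length + 2.0 * np.pi * radius
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": 4.0 * np.pi * area / perimeter**2,
    }
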