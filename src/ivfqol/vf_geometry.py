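"""Humphrey Field Analyzer test-point grids and subfield schemes.

The 10-2 program samples the central 10 degrees on a 2-degree lattice (68
points); the 24-2 program samples the central 24 degrees on a 6-degree
lattice (52 symmetric points plus two nasal-step points, 54 in total).
Coordinates are visual-space degrees with fixation at the origin:
positive x is to the patient's right, positive y is superior.  Both eyes
are expressed in the same visual-space frame, so corresponding binocular
locations share coordinates and no retinal flip is ever applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

PATTERN_10_2 = "10-2"
PATTERN_24_2 = "24-2"
SUPPORTED_PATTERNS = (PATTERN_10_2, PATTERN_24_2)

#: quadrant subfield labels used for the central 10-2 field
QUADRANT_LABELS = (
    "inner_upper_right",
    "outer_upper_right",
    "inner_upper_left",
    "outer_upper_left",
    "inner_lower_left",
    "outer_lower_left",
    "inner_lower_right",
    "outer_lower_right",
)

#: hemifield labels used for the 24-2 field
HEMIFIELD_LABELS = ("upper", "lower")


class GeometryError(ValueError):
    """Raised for unsupported patterns, lateralities or scheme mismatches."""


@dataclass(frozen=True, order=True)
class TestPoint:
    """A single perimetric stimulus location in visual-space degrees."""

    x: int
    y: int
    pattern: str

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class TestPointGrid:
    """Ordered set of test points for one pattern (and eye, for 24-2)."""

    pattern: str
    points: tuple[TestPoint, ...]
    laterality: str | None = None  # "right"/"left"; None for 10-2

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def index(self) -> dict[tuple[int, int], int]:
        """Position of each (x, y) coordinate in the point order."""
        return {(p.x, p.y): i for i, p in enumerate(self.points)}

    def to_dataframe(self, scheme: "SubfieldScheme | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "pattern": [p.pattern for p in self.points],
                "x_deg": [p.x for p in self.points],
                "y_deg": [p.y for p in self.points],
            }
        )
        if scheme is not None:
            labels = assign_subfields(self, scheme)
            df["subfield_label"] = [labels[p] for p in self.points]
        return df

    def to_csv(self, path, scheme: "SubfieldScheme | None" = None) -> None:
        self.to_dataframe(scheme).to_csv(path, index=False)

    def to_json(self, path, scheme: "SubfieldScheme | None" = None) -> None:
        records = self.to_dataframe(scheme).to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump({"pattern": self.pattern, "laterality": self.laterality,
                       "points": records}, fh, indent=1)


@dataclass(frozen=True)
class SubfieldScheme:
    """Partition of a grid into labelled subfields.

    The 10-2 scheme crosses an inner/outer split at ``inner_radius``
    degrees of eccentricity (inclusive on the inner side) with the four
    quadrants given by the signs of x and y.  The 24-2 scheme splits into
    upper and lower hemifields on the sign of y.  No default grid point
    lies on an axis or exactly at 5 degrees, so assignment is never tied.
    """

    name: str = "quadrants_10_2"
    pattern: str = PATTERN_10_2
    inner_radius: float = 5.0
    metric: str = "euclidean"  # or "chebyshev"
    labels: tuple[str, ...] = field(default=QUADRANT_LABELS)

    def eccentricity(self, point: TestPoint) -> float:
        if self.metric == "chebyshev":
            return float(max(abs(point.x), abs(point.y)))
        return point.eccentricity


def default_scheme(pattern: str) -> SubfieldScheme:
    """The analysis default: 8 quadrant subfields (10-2) or hemifields (24-2)."""
    if pattern == PATTERN_10_2:
        return SubfieldScheme()
    if pattern == PATTERN_24_2:
        return SubfieldScheme(name="hemifields_24_2", pattern=PATTERN_24_2,
                              labels=HEMIFIELD_LABELS)
    raise GeometryError(f"unsupported pattern: {pattern!r}")


def _points_10_2() -> list[tuple[int, int]]:
    # odd coordinates on the 2-degree lattice, inside x^2 + y^2 <= 82;
    # this is the unique such rule giving the printed 68-point count
    pts = [
        (x, y)
        for x in range(-9, 10, 2)
        for y in range(-9, 10, 2)
        if x * x + y * y <= 82
    ]
    assert len(pts) == 68
    return pts


_ROWS_24_2 = {21: (3, 9), 15: (3, 9, 15), 9: (3, 9, 15, 21), 3: (3, 9, 15, 21)}


def _points_24_2(laterality: str) -> list[tuple[int, int]]:
    pts = [
        (sx * ax, sy * ay)
        for ay, axs in _ROWS_24_2.items()
        for ax in axs
        for sx in (-1, 1)
        for sy in (-1, 1)
    ]
    # nasal step: nasal visual field is contralateral to the tested eye
    nasal_x = -27 if laterality == "right" else 27
    pts += [(nasal_x, 3), (nasal_x, -3)]
    assert len(pts) == 54
    return pts


def generate_grid(pattern: str, laterality: str | None = None) -> TestPointGrid:
    """Generate the standard test-point layout for a pattern.

    Parameters
    ----------
    pattern : {"10-2", "24-2"}
    laterality : {"right", "left"}, required for 24-2
        Orients the two nasal-step points (nasal field is on the side of
        the nose, i.e. left in visual space for the right eye).
    """
    if pattern == PATTERN_10_2:
        coords = _points_10_2()
        lat = None
    elif pattern == PATTERN_24_2:
        if laterality not in ("right", "left"):
            raise GeometryError(
                "24-2 grid requires laterality 'right' or 'left' "
                f"(got {laterality!r})"
            )
        coords = _points_24_2(laterality)
        lat = laterality
    else:
        raise GeometryError(f"unsupported pattern: {pattern!r}")
    coords.sort(key=lambda c: (-c[1], c[0]))  # top row first, left to right
    points = tuple(TestPoint(x, y, pattern) for x, y in coords)
    return TestPointGrid(pattern=pattern, points=points, laterality=lat)


def assign_subfields(grid: TestPointGrid,
                     scheme: SubfieldScheme) -> dict[TestPoint, str]:
    """Map every grid point to exactly one subfield label."""
    if scheme.pattern != grid.pattern:
        raise GeometryError(
            f"scheme for pattern {scheme.pattern!r} applied to "
            f"{grid.pattern!r} grid"
        )
    out: dict[TestPoint, str] = {}
    if grid.pattern == PATTERN_24_2:
        for p in grid:
            out[p] = "upper" if p.y > 0 else "lower"
        return out
    for p in grid:
        ring = "inner" if scheme.eccentricity(p) <= scheme.inner_radius else "outer"
        vert = "upper" if p.y > 0 else "lower"
        horiz = "right" if p.x > 0 else "left"
        out[p] = f"{ring}_{vert}_{horiz}"
    return out


def corresponding_points(
    grid_od: TestPointGrid, grid_os: TestPointGrid
) -> tuple[list[tuple[TestPoint, TestPoint]], list[TestPoint], list[TestPoint]]:
    """Match points of two grids by identical visual-space coordinates.

    Returns (matched pairs, unmatched OD points, unmatched OS points).
    Two 10-2 grids match completely; for 24-2 the nasal-step points are
    mirror-opposite between eyes and come back unmatched.
    """
    if grid_od.pattern != grid_os.pattern:
        raise GeometryError(
            f"cannot match {grid_od.pattern!r} against {grid_os.pattern!r}"
        )
    os_by_coord = {(p.x, p.y): p for p in grid_os}
    pairs: list[tuple[TestPoint, TestPoint]] = []
    unmatched_od: list[TestPoint] = []
    for p in grid_od:
        q = os_by_coord.pop((p.x, p.y), None)
        if q is None:
            unmatched_od.append(p)
        else:
            pairs.append((p, q))
    unmatched_os = [p for p in grid_os if (p.x, p.y) in os_by_coord]
    return pairs, unmatched_od, unmatched_os


def subfield_point_counts(grid: TestPointGrid,
                          scheme: SubfieldScheme) -> dict[str, int]:
    counts: dict[str, int] = {lab: 0 for lab in scheme.labels}
    for lab in assign_subfields(grid, scheme).values():
        counts[lab] += 1
    return counts
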