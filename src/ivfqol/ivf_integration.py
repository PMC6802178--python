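"""Binocular integration of per-eye total-deviation fields.

A monocular Humphrey field carries a total-deviation (TD) value, in dB
relative to the age-corrected normal, at every test point of its pattern.
The binocular integrated visual field (IVF) combines the two eyes.  The
best-location model records the better (larger) TD of the two corresponding
locations; the binocular-summation alternative combines linearised
sensitivities quadratically.  TD values, not raw sensitivities, are
integrated under the best-location model.

24-2 nasal-step points have no corresponding location in the fellow eye;
the integrated field carries the single available eye's value there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .vf_geometry import (
    SubfieldScheme,
    TestPointGrid,
    assign_subfields,
    corresponding_points,
    default_scheme,
    generate_grid,
)

BEST_LOCATION = "best_location"
BINOCULAR_SUMMATION = "binocular_summation"


class IntegrationError(ValueError):
    """Pattern/patient mismatches and incomplete fields."""


@dataclass(frozen=True)
class Reliability:
    """Per-test reliability indices, as fractions in [0, 1]."""

    fixation_loss: float = 0.0
    false_positive: float = 0.0
    false_negative: float = 0.0


@dataclass(frozen=True)
class MonocularField:
    """One eye's TD map over a grid, with test metadata.

    ``td`` is aligned with ``grid.points`` order.
    """

    patient_id: str
    eye: str  # "OD" or "OS"
    date: str  # ISO-8601
    grid: TestPointGrid
    td: np.ndarray
    reliability: Reliability = field(default_factory=Reliability)
    md: float = float("nan")

    def __post_init__(self):
        td = np.asarray(self.td, dtype=float)
        object.__setattr__(self, "td", td)
        if td.shape != (len(self.grid),):
            raise IntegrationError(
                f"TD array of length {td.shape} does not cover the "
                f"{len(self.grid)}-point {self.grid.pattern} grid"
            )
        if not np.all(np.isfinite(td)):
            raise IntegrationError("TD values must be finite at every point")

    @property
    def pattern(self) -> str:
        return self.grid.pattern


@dataclass(frozen=True)
class BinocularIntegratedField:
    patient_id: str
    grid: TestPointGrid  # visual-space union of the two eyes' layouts
    td: np.ndarray
    model: str = BEST_LOCATION

    @property
    def pattern(self) -> str:
        return self.grid.pattern


@dataclass(frozen=True)
class SubfieldSummary:
    """Per-subfield mean TD (mTD, dB) and point counts, plus the whole-field mean."""

    mtd: dict[str, float]
    counts: dict[str, int]
    whole_field_mtd: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.mtd)


def _union_grid(field_od: MonocularField, field_os: MonocularField):
    """Matched index pairs and the point list of the integrated field."""
    pairs, un_od, un_os = corresponding_points(field_od.grid, field_os.grid)
    idx_od = field_od.grid.index()
    idx_os = field_os.grid.index()
    points = [p for p, _ in pairs] + un_od + [
        # re-tag unmatched OS points with the union pattern
        q for q in un_os
    ]
    sources = (
        [("both", idx_od[(p.x, p.y)], idx_os[(p.x, p.y)]) for p, _ in pairs]
        + [("od", idx_od[(p.x, p.y)], -1) for p in un_od]
        + [("os", -1, idx_os[(q.x, q.y)]) for q in un_os]
    )
    grid = TestPointGrid(pattern=field_od.pattern, points=tuple(points),
                         laterality=None)
    return grid, sources


def _check_compatible(field_od: MonocularField, field_os: MonocularField):
    if field_od.pattern != field_os.pattern:
        raise IntegrationError(
            f"pattern mismatch: {field_od.pattern} vs {field_os.pattern}"
        )
    if field_od.patient_id != field_os.patient_id:
        raise IntegrationError(
            f"patient mismatch: {field_od.patient_id} vs {field_os.patient_id}"
        )


def integrate_best_location(field_od: MonocularField,
                            field_os: MonocularField) -> BinocularIntegratedField:
    """Best-location IVF: per-point maximum TD over the two eyes."""
    _check_compatible(field_od, field_os)
    grid, sources = _union_grid(field_od, field_os)
    td = np.empty(len(grid))
    for k, (src, i, j) in enumerate(sources):
        if src == "both":
            td[k] = max(field_od.td[i], field_os.td[j])
        elif src == "od":
            td[k] = field_od.td[i]
        else:
            td[k] = field_os.td[j]
    return BinocularIntegratedField(field_od.patient_id, grid, td, BEST_LOCATION)


def integrate_binocular_summation(
    field_od: MonocularField, field_os: MonocularField, q: float = 2.0
) -> BinocularIntegratedField:
    """Quadratic binocular summation on linearised sensitivities.

    dB deviations are linearised as 10**(TD/10), combined as
    (s_od**q + s_os**q)**(1/q) and re-expressed in dB.  With q = 2 two
    equal eyes gain 10*log10(sqrt(2)) ~ 1.5 dB over either alone.
    """
    _check_compatible(field_od, field_os)
    grid, sources = _union_grid(field_od, field_os)
    td = np.empty(len(grid))
    for k, (src, i, j) in enumerate(sources):
        if src == "both":
            s_od = 10.0 ** (field_od.td[i] / 10.0)
            s_os = 10.0 ** (field_os.td[j] / 10.0)
            td[k] = 10.0 * np.log10((s_od**q + s_os**q) ** (1.0 / q))
        elif src == "od":
            td[k] = field_od.td[i]
        else:
            td[k] = field_os.td[j]
    return BinocularIntegratedField(field_od.patient_id, grid, td,
                                    BINOCULAR_SUMMATION)


def average_fields(f1: BinocularIntegratedField,
                   f2: BinocularIntegratedField) -> BinocularIntegratedField:
    """Per-point mean of two IVFs (the two assessments around the VRQoL date)."""
    if f1.pattern != f2.pattern or f1.patient_id != f2.patient_id \
            or f1.model != f2.model:
        raise IntegrationError("averaged fields must share pattern, patient and model")
    idx2 = f2.grid.index()
    order = [idx2[(p.x, p.y)] for p in f1.grid]
    if len(order) != len(f2.grid):
        raise IntegrationError("averaged fields must share point layouts")
    td = (f1.td + f2.td[order]) / 2.0
    return BinocularIntegratedField(f1.patient_id, f1.grid, td, f1.model)


def average_available(fields: list[BinocularIntegratedField]) -> BinocularIntegratedField:
    """Average however many assessments exist; warn when fewer than two."""
    if not fields:
        raise IntegrationError("no integrated fields to average")
    if len(fields) == 1:
        warnings.warn(
            "only one integrated assessment available; expected two around "
            "the questionnaire date", stacklevel=2)
        return fields[0]
    out = fields[0]
    for f in fields[1:]:
        out = average_fields(out, f)
    if len(fields) > 2:  # sequential pairwise averaging is not the mean for >2
        idx = out.grid.index()
        acc = np.zeros(len(out.grid))
        for f in fields:
            order = [f.grid.index()[(p.x, p.y)] for p in out.grid]
            acc += f.td[order]
        out = replace(out, td=acc / len(fields))
    return out


def subfield_mtd(ivf: BinocularIntegratedField,
                 scheme: SubfieldScheme | None = None) -> SubfieldSummary:
    """Arithmetic-mean TD per subfield label, plus the whole-field mTD."""
    if scheme is None:
        scheme = default_scheme(ivf.pattern)
    labels = assign_subfields(ivf.grid, scheme)
    lab_arr = np.array([labels[p] for p in ivf.grid])
    mtd: dict[str, float] = {}
    counts: dict[str, int] = {}
    for lab in scheme.labels:
        mask = lab_arr == lab
        counts[lab] = int(mask.sum())
        mtd[lab] = float(ivf.td[mask].mean()) if counts[lab] else float("nan")
    return SubfieldSummary(mtd=mtd, counts=counts,
                           whole_field_mtd=float(ivf.td.mean()))


# ---------------------------------------------------------------- CSV I/O

FIELD_CSV_COLUMNS = [
    "patient_id", "eye", "date", "pattern", "x_deg", "y_deg", "td_db",
    "fl_rate", "fp_rate", "fn_rate", "md_db",
]


def fields_to_dataframe(fields: list[MonocularField]) -> pd.DataFrame:
    rows = []
    for f in fields:
        for p, td in zip(f.grid, f.td):
            rows.append({
                "patient_id": f.patient_id, "eye": f.eye, "date": f.date,
                "pattern": f.pattern, "x_deg": p.x, "y_deg": p.y,
                "td_db": td, "fl_rate": f.reliability.fixation_loss,
                "fp_rate": f.reliability.false_positive,
                "fn_rate": f.reliability.false_negative, "md_db": f.md,
            })
    return pd.DataFrame(rows, columns=FIELD_CSV_COLUMNS)


def fields_from_dataframe(df: pd.DataFrame) -> list[MonocularField]:
    fields = []
    for (pid, eye, date, pattern), g in df.groupby(
            ["patient_id", "eye", "date", "pattern"], sort=False):
        laterality = None
        if pattern == "24-2":
            laterality = "right" if eye == "OD" else "left"
        grid = generate_grid(pattern, laterality)
        coord_td = {(int(r.x_deg), int(r.y_deg)): r.td_db for r in g.itertuples()}
        try:
            td = np.array([coord_td[(p.x, p.y)] for p in grid])
        except KeyError as exc:
            raise IntegrationError(
                f"field {pid}/{eye}/{date} is missing point {exc}"
            ) from exc
        rel = Reliability(float(g.fl_rate.iloc[0]), float(g.fp_rate.iloc[0]),
                          float(g.fn_rate.iloc[0]))
        fields.append(MonocularField(str(pid), eye, str(date), grid, td,
                                     rel, float(g.md_db.iloc[0])))
    return fields


def read_fields_csv(path) -> list[MonocularField]:
    return fields_from_dataframe(pd.read_csv(path))


def write_fields_csv(fields: list[MonocularField], path) -> None:
    fields_to_dataframe(fields).to_csv(path, index=False)
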