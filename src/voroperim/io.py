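"""Reading, writing and normalizing perimetry test patterns and visual-field tables.

A *test pattern* is the fixed set of retinal locations probed by a perimeter
program (e.g. the Humphrey 24-2 grid or the OCTOPUS G1 program).  A *visual
field record* is one examination of one eye: a vector of sensitivity
deviations, one per pattern location, in dB.  The sign convention throughout
the package is ``deviation = measured - age-normal``, so loss is negative and
the mean defect MD = -mean(deviation) is positive under loss.

File dialects
-------------
Pattern CSV: header ``index,x_deg,y_deg,blind_spot``; one row per location;
the 0-based ``index`` column defines the order of the deviation vector.

VF table CSV: header ``subject_id,eye,group,pattern_id,d_0,...,d_{L-1}``;
``eye`` is OD (right) or OS (left); ``group`` is ``control``, ``EG`` or
``NA`` when unlabeled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

EYES = ("OD", "OS")
GROUPS = ("control", "EG")
COORD_LIMIT = 30.0  # degrees; the representable half-width of the field

_PATTERN_FILES = {"24-2": "hfa_24_2.csv", "G1": "g1_synthetic.csv"}


class PerimetryIOError(ValueError):
    """Raised for malformed pattern or visual-field files."""


@dataclass(frozen=True)
class TestPattern:
    """An ordered set of perimetric test locations.

    Parameters
    ----------
    pattern_id:
        Short name, e.g. ``"24-2"`` or ``"G1"``.
    x, y:
        Location coordinates in degrees of visual angle, right-eye (OD)
        orientation: positive x temporal, positive y superior.
    blind_spot:
        Boolean flags marking locations that fall on the physiological blind
        spot; these are excluded from global indices and (by default) from
        voronoi seeding.
    """

    __test__ = False  # despite the name, not a pytest class

    pattern_id: str
    x: np.ndarray
    y: np.ndarray
    blind_spot: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "blind_spot", np.asarray(self.blind_spot, dtype=bool))
        if self.x.ndim != 1 or self.x.shape != self.y.shape or self.x.shape != self.blind_spot.shape:
            raise PerimetryIOError("pattern coordinate arrays must be 1-D and equally long")
        if self.L < 1:
            raise PerimetryIOError("a pattern needs at least one location")
        if np.any(np.abs(self.x) > COORD_LIMIT) or np.any(np.abs(self.y) > COORD_LIMIT):
            bad = int(np.argmax((np.abs(self.x) > COORD_LIMIT) | (np.abs(self.y) > COORD_LIMIT)))
            raise PerimetryIOError(
                f"location {bad} at ({self.x[bad]}, {self.y[bad]}) lies outside "
                f"[-{COORD_LIMIT:g}, {COORD_LIMIT:g}] degrees"
            )
        coords = {(float(a), float(b)) for a, b in zip(self.x, self.y)}
        if len(coords) != self.L:
            raise PerimetryIOError("pattern contains duplicate coordinates")

    @property
    def L(self) -> int:
        """Number of test locations (length of the deviation vector)."""
        return self.x.size

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of locations that are not blind-spot locations."""
        return ~self.blind_spot

    def mirrored(self) -> "TestPattern":
        """The same pattern mirrored about the vertical axis (x -> -x).

        Used to view a left-eye (OS) examination in right-eye orientation;
        location order, blind-spot flags and hence deviation alignment are
        preserved.
        """
        return TestPattern(self.pattern_id, -self.x, self.y.copy(), self.blind_spot.copy())


@dataclass
class VisualFieldRecord:
    """One perimetric examination of one eye.

    ``deviations`` holds measured-minus-normal sensitivities in dB, aligned
    to the pattern's location order; loss is negative.  ``group`` may be
    ``None`` for unlabeled (inference-time) records.
    """

    subject_id: str
    eye: str
    pattern_id: str
    deviations: np.ndarray
    group: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise PerimetryIOError(f"unknown eye code {self.eye!r}; expected OD or OS")
        if self.group is not None and self.group not in GROUPS:
            raise PerimetryIOError(f"unknown group {self.group!r}; expected control or EG")
        self.deviations = np.asarray(self.deviations, dtype=float)
        if self.deviations.ndim != 1:
            raise PerimetryIOError("deviations must be a 1-D vector")
        if not np.all(np.isfinite(self.deviations)):
            raise PerimetryIOError("deviations must be finite")

    def usable_deviations(self, pattern: TestPattern) -> np.ndarray:
        """Deviations at non-blind-spot locations, for index computation."""
        self._check_pattern(pattern)
        return self.deviations[pattern.usable]

    def _check_pattern(self, pattern: TestPattern) -> None:
        if self.deviations.size != pattern.L:
            raise PerimetryIOError(
                f"record has {self.deviations.size} deviations but pattern "
                f"{pattern.pattern_id!r} defines {pattern.L} locations"
            )


def load_pattern(path) -> TestPattern:
    """Load a test pattern from its CSV definition.

    Raises :class:`PerimetryIOError` naming the offending row for missing
    columns, duplicate coordinates or out-of-range coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["index", "x_deg", "y_deg", "blind_spot"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PerimetryIOError(f"{path.name}: missing pattern columns {missing}")
    df = df.sort_values("index").reset_index(drop=True)
    if not np.array_equal(df["index"].to_numpy(), np.arange(len(df))):
        raise PerimetryIOError(f"{path.name}: index column must be 0..L-1 without gaps")
    for row in df.itertuples():
        if abs(row.x_deg) > COORD_LIMIT or abs(row.y_deg) > COORD_LIMIT:
            raise PerimetryIOError(
                f"{path.name}: row {row.Index} at ({row.x_deg}, {row.y_deg}) "
                f"is outside [-{COORD_LIMIT:g}, {COORD_LIMIT:g}] degrees"
            )
    try:
        return TestPattern(
            pattern_id=path.stem,
            x=df["x_deg"].to_numpy(float),
            y=df["y_deg"].to_numpy(float),
            blind_spot=df["blind_spot"].to_numpy().astype(bool),
        )
    except PerimetryIOError as err:
        raise PerimetryIOError(f"{path.name}: {err}") from None


def write_pattern(pattern: TestPattern, path) -> None:
    """Write a pattern in the CSV dialect accepted by :func:`load_pattern`."""
    df = pd.DataFrame(
        {
            "index": np.arange(pattern.L),
            "x_deg": pattern.x,
            "y_deg": pattern.y,
            "blind_spot": pattern.blind_spot.astype(int),
        }
    )
    df.to_csv(path, index=False)


def bundled_pattern(name: str) -> TestPattern:
    """Return a pattern shipped with the package: ``"24-2"`` or ``"G1"``.

    The 24-2 file follows the standard published Humphrey grid (54 locations,
    two flagged as blind spot at (15, +/-3) in OD orientation).  The G1 file
    is a synthetic 59-location stand-in laid out like the OCTOPUS G program
    (centrally condensed rings); the exact clinical chart coordinates are not
    reproduced.
    """
    if name not in _PATTERN_FILES:
        raise PerimetryIOError(f"no bundled pattern {name!r}; available: {sorted(_PATTERN_FILES)}")
    ref = importlib.resources.files("voroperim.patterns") / _PATTERN_FILES[name]
    with importlib.resources.as_file(ref) as p:
        pattern = load_pattern(p)
    return replace_pattern_id(pattern, name)


def replace_pattern_id(pattern: TestPattern, pattern_id: str) -> TestPattern:
    return TestPattern(pattern_id, pattern.x, pattern.y, pattern.blind_spot)


def load_vf_table(path, pattern: TestPattern) -> list[VisualFieldRecord]:
    """Load visual-field records from a VF table CSV.

    The table must carry exactly ``pattern.L`` deviation columns
    ``d_0 .. d_{L-1}``; each offending row is reported by index.  OS rows are
    *not* auto-flipped — laterality normalization is an explicit step
    (:func:`flip_to_right_eye`).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    base_cols = ["subject_id", "eye", "group", "pattern_id"]
    missing = [c for c in base_cols if c not in df.columns]
    if missing:
        raise PerimetryIOError(f"{path.name}: missing columns {missing}")
    dev_cols = [c for c in df.columns if c.startswith("d_")]
    expected = [f"d_{i}" for i in range(pattern.L)]
    if dev_cols != expected:
        raise PerimetryIOError(
            f"{path.name}: expected deviation columns d_0..d_{pattern.L - 1} "
            f"for pattern {pattern.pattern_id!r}, found {len(dev_cols)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = np.asarray([getattr(row, c) for c in expected], dtype=object)
        try:
            deviations = values.astype(float)
        except (TypeError, ValueError):
            raise PerimetryIOError(f"{path.name}: row {i}: non-numeric deviation value") from None
        group = None if pd.isna(row.group) or row.group == "NA" else str(row.group)
        try:
            rec = VisualFieldRecord(
                subject_id=str(row.subject_id),
                eye=str(row.eye),
                pattern_id=str(row.pattern_id),
                deviations=deviations,
                group=group,
            )
        except PerimetryIOError as err:
            raise PerimetryIOError(f"{path.name}: row {i}: {err}") from None
        records.append(rec)
    return records


def write_vf_table(records: list[VisualFieldRecord], path) -> None:
    """Write records in the VF table CSV dialect (round-trips with load)."""
    if not records:
        raise PerimetryIOError("cannot write an empty record list")
    L = records[0].deviations.size
    rows = []
    for rec in records:
        if rec.deviations.size != L:
            raise PerimetryIOError("all records in one table must share a pattern length")
        row = {
            "subject_id": rec.subject_id,
            "eye": rec.eye,
            "group": rec.group if rec.group is not None else "NA",
            "pattern_id": rec.pattern_id,
        }
        row.update({f"d_{i}": rec.deviations[i] for i in range(L)})
        rows.append(row)
    # default float formatting is the shortest round-trip repr: exact reload
    pd.DataFrame(rows).to_csv(path, index=False)


def flip_to_right_eye(
    record: VisualFieldRecord, pattern: TestPattern
) -> tuple[VisualFieldRecord, TestPattern]:
    """Normalize an examination to right-eye (OD) orientation.

    OD records are returned unchanged with the original pattern.  OS records
    are mirrored about the vertical axis: every location's x-coordinate is
    negated, the eye is relabeled OD, and deviation values stay attached to
    their (now mirrored) locations.  Applying the coordinate mirror twice
    restores the original pattern.
    """
    record._check_pattern(pattern)
    if record.eye == "OD":
        return record, pattern
    flipped = replace(record, eye="OD", deviations=record.deviations.copy())
    return flipped, pattern.mirrored()
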