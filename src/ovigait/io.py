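"""Trial containers and marker-trajectory I/O.

Positions are stored in millimetres in the capture volume's global
coordinate system.  The axis convention lives once on :class:`Trial` (as an
:class:`AxesConvention`) and every downstream module reads axis indices from
there rather than hard-coding them.

The native on-disk format is a TSV dialect: UTF-8, tab-separated, header
``frame\ttime\t<LABEL>_x\t<LABEL>_y\t<LABEL>_z ...``, coordinates in mm,
blank cells marking occluded frames, one file per walking pass.  C3D files
can be read/written when the optional ``ezc3d`` dependency is installed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .markers import FULL_MARKER_SET, REQUIRED_MARKERS

SESSIONS = ("B1", "B2", "B3", "D3")  # 8-, 5-, 1-day pre-stroke; 3-day post
BASELINE_SESSIONS = ("B1", "B2", "B3")

STUDY_TABLE_COLUMNS = ("animal", "session", "limb", "measure", "value", "units")


class FormatError(ValueError):
    """Raised when a trial file cannot be parsed in the requested format."""


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass(frozen=True)
class AxesConvention:
    """Global coordinate system: z vertical up, y progression, x lateral.

    ``x`` is positive toward the animal's right.
    """

    lateral: int = 0
    progression: int = 1
    vertical: int = 2

    @property
    def sagittal(self) -> tuple[int, int]:
        """(progression, vertical) index pair defining the sagittal plane."""
        return (self.progression, self.vertical)


@dataclass
class MarkerTrajectory:
    """One labelled marker: per-frame 3-vectors (mm) plus an occlusion mask."""

    label: str
    positions: np.ndarray  # (n_frames, 3) float, mm
    occluded: np.ndarray | None = None  # (n_frames,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError(
                f"{self.label}: positions must be (n_frames, 3), got {self.positions.shape}"
            )
        n = self.positions.shape[0]
        if n < 2:
            raise ValidationError(f"{self.label}: need at least 2 frames, got {n}")
        if self.occluded is None:
            self.occluded = np.zeros(n, dtype=bool)
        else:
            self.occluded = np.asarray(self.occluded, dtype=bool)
            if self.occluded.shape != (n,):
                raise ValidationError(f"{self.label}: occlusion mask length mismatch")
        if not np.all(np.isfinite(self.positions[~self.occluded])):
            raise ValidationError(f"{self.label}: non-finite coordinates in visible frames")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "MarkerTrajectory":
        return MarkerTrajectory(self.label, self.positions.copy(), self.occluded.copy())


@dataclass
class Trial:
    """One walking pass: labelled trajectories at a fixed sample rate."""

    animal_id: str
    session: str
    sample_rate: float = 200.0
    markers: dict[str, MarkerTrajectory] = field(default_factory=dict)
    axes: AxesConvention = field(default_factory=AxesConvention)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        counts = {m.n_frames for m in self.markers.values()}
        if len(counts) > 1:
            raise ValidationError(f"frame-count mismatch across markers: {sorted(counts)}")

    @property
    def n_frames(self) -> int:
        if not self.markers:
            return 0
        return next(iter(self.markers.values())).n_frames

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame / sample_rate, 0-based)."""
        return np.arange(self.n_frames) / self.sample_rate

    def marker(self, label: str) -> MarkerTrajectory:
        try:
            return self.markers[label]
        except KeyError:
            raise ValidationError(f"trial has no marker {label!r}") from None

    def require(self, *labels: str) -> None:
        missing = [m for m in labels if m not in self.markers]
        if missing:
            raise ValidationError(f"missing required markers: {missing}")

    def map_markers(self, fn) -> "Trial":
        """New Trial with ``fn`` applied to every trajectory."""
        return replace(self, markers={k: fn(v) for k, v in self.markers.items()})


@dataclass(frozen=True)
class ValidationReport:
    analysis: str
    missing: tuple[str, ...]
    extra: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.missing


def validate_marker_set(trial: Trial, analysis: str = "full", side: str | None = None) -> ValidationReport:
    """Report missing/extra labels for the marker subset an analysis needs.

    ``analysis`` is one of global/forelimb/hindlimb/full; limb analyses take
    ``side`` ("L"/"R"); omitting it requires both sides.
    """
    req = REQUIRED_MARKERS[analysis]
    if isinstance(req, dict):
        if side is not None:
            required = req[side]
        else:
            required = tuple(m for s in ("L", "R") for m in req[s])
    else:
        required = req
    present = set(trial.markers)
    missing = tuple(m for m in required if m not in present)
    extra = tuple(sorted(present - set(FULL_MARKER_SET)))
    return ValidationReport(analysis=analysis, missing=missing, extra=extra)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _tsv_header(labels: list[str]) -> list[str]:
    cols = ["frame", "time"]
    for lab in labels:
        cols += [f"{lab}_x", f"{lab}_y", f"{lab}_z"]
    return cols


def write_trial(trial: Trial, path, format: str = "tsv") -> None:
    """Serialize a trial; round-trips positions to 1e-6 mm and masks exactly."""
    if not trial.markers:
        raise ValidationError("cannot write a trial with no markers")
    if format == "tsv":
        _write_tsv(trial, path)
    elif format == "c3d":
        _write_c3d(trial, path)
    else:
        raise FormatError(f"unknown format {format!r}")


def load_trial(path, format: str = "tsv", animal_id: str = "", session: str = "") -> Trial:
    """Load a trial file; occlusion masks are set where the source marks gaps."""
    if format == "tsv":
        return _read_tsv(path, animal_id=animal_id, session=session)
    if format == "c3d":
        return _read_c3d(path, animal_id=animal_id, session=session)
    raise FormatError(f"unknown format {format!r}")


def _write_tsv(trial: Trial, path) -> None:
    labels = list(trial.markers)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["# animal", trial.animal_id, "session", trial.session,
                    "sample_rate", repr(trial.sample_rate)])
        w.writerow(_tsv_header(labels))
        for i in range(trial.n_frames):
            row = [str(i), repr(i / trial.sample_rate)]
            for lab in labels:
                tr = trial.markers[lab]
                if tr.occluded[i]:
                    row += ["", "", ""]
                else:
                    row += [repr(float(c)) for c in tr.positions[i]]
            w.writerow(row)


def _read_tsv(path, animal_id: str = "", session: str = "") -> Trial:
    sample_rate = 200.0
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            first = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if first and first[0].startswith("#"):
            meta = first
            animal_id = animal_id or (meta[1] if len(meta) > 1 else "")
            session = session or (meta[3] if len(meta) > 3 else "")
            if len(meta) > 5:
                sample_rate = float(meta[5])
            header = next(reader, None)
        else:
            header = first
        if not header or header[:2] != ["frame", "time"]:
            raise FormatError(f"{path}: not a trial TSV (bad header)")
        coord_cols = header[2:]
        if len(coord_cols) % 3:
            raise FormatError(f"{path}: coordinate columns not in xyz triples")
        labels = []
        for j in range(0, len(coord_cols), 3):
            triple = coord_cols[j:j + 3]
            stems = {c.rsplit("_", 1)[0] for c in triple}
            suffixes = [c.rsplit("_", 1)[1] for c in triple]
            if len(stems) != 1 or suffixes != ["x", "y", "z"]:
                raise FormatError(f"{path}: malformed coordinate triple {triple}")
            labels.append(stems.pop())
        rows = [r for r in reader if r]
    n = len(rows)
    markers: dict[str, MarkerTrajectory] = {}
    data = np.full((n, len(labels), 3), np.nan)
    occ = np.zeros((n, len(labels)), dtype=bool)
    for i, row in enumerate(rows):
        vals = row[2:]
        for j in range(len(labels)):
            cell = vals[3 * j:3 * j + 3]
            if any(c.strip() == "" for c in cell):
                occ[i, j] = True
            else:
                data[i, j] = [float(c) for c in cell]
    unknown = [lab for lab in labels if lab not in FULL_MARKER_SET]
    if unknown:
        warnings.warn(f"unknown marker labels retained under raw names: {unknown}")
    for j, lab in enumerate(labels):
        markers[lab] = MarkerTrajectory(lab, data[:, j, :], occ[:, j])
    return Trial(animal_id=animal_id, session=session, sample_rate=sample_rate,
                 markers=markers)


# ---------------------------------------------------------------------------
# C3D (optional)
# ---------------------------------------------------------------------------

def _require_ezc3d():
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "C3D support requires the optional 'ezc3d' package; "
            "install ovigait[c3d] or use the TSV format"
        ) from exc
    return ezc3d


def _write_c3d(trial: Trial, path) -> None:  # pragma: no cover - optional
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d()
    labels = list(trial.markers)
    n = trial.n_frames
    pts = np.zeros((4, len(labels), n))
    for j, lab in enumerate(labels):
        tr = trial.markers[lab]
        pts[:3, j, :] = tr.positions.T
        pts[3, j, :] = np.where(tr.occluded, -1.0, 1.0)
        pts[:3, j, tr.occluded] = 0.0
    c3d["parameters"]["POINT"]["LABELS"]["value"] = labels
    c3d["parameters"]["POINT"]["RATE"]["value"] = np.array([trial.sample_rate])
    c3d["parameters"]["POINT"]["UNITS"]["value"] = ["mm"]
    c3d["data"]["points"] = pts
    c3d.write(str(path))


def _read_c3d(path, animal_id: str = "", session: str = "") -> Trial:  # pragma: no cover
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d(str(path))
    labels = c3d["parameters"]["POINT"]["LABELS"]["value"]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = c3d["data"]["points"]
    markers = {}
    for j, lab in enumerate(labels):
        pos = pts[:3, j, :].T.astype(float)
        occl = pts[3, j, :] < 0
        pos[occl] = np.nan
        markers[lab] = MarkerTrajectory(lab, pos, occl)
    unknown = [lab for lab in labels if lab not in FULL_MARKER_SET]
    if unknown:
        warnings.warn(f"unknown marker labels retained under raw names: {unknown}")
    return Trial(animal_id=animal_id, session=session, sample_rate=rate, markers=markers)


# ---------------------------------------------------------------------------
# StudyTable
# ---------------------------------------------------------------------------

class StudyTable:
    """Long-format study measurements: one row per (animal, session, limb, measure).

    ``limb`` is empty for global (whole-trial) measures.  Units are attached
    per row; values are in the reporting units (cm, m/s, s, degrees), the
    mm-internal convention applies only to marker data.
    """

    def __init__(self, df):
        import pandas as pd

        df = pd.DataFrame(df, columns=list(STUDY_TABLE_COLUMNS))
        key = ["animal", "session", "limb", "measure"]
        if df.duplicated(subset=key).any():
            dupes = df[df.duplicated(subset=key, keep=False)]
            raise ValidationError(
                f"duplicate (animal, session, limb, measure) rows:\n{dupes.head()}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StudyTable":
        import pandas as pd

        df = pd.read_csv(path, keep_default_na=False,
                         dtype={"animal": str, "session": str, "limb": str})
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        return cls(df)

    @classmethod
    def from_rows(cls, rows) -> "StudyTable":
        import pandas as pd

        return cls(pd.DataFrame(rows, columns=list(STUDY_TABLE_COLUMNS)))

    def measure(self, measure: str, limb: str | None = None):
        """Wide per-(animal, session) view of one measure."""
        df = self.df[self.df["measure"] == measure]
        if limb is not None:
            df = df[df["limb"] == limb]
        return df

    def concat(self, other: "StudyTable") -> "StudyTable":
        import pandas as pd

        return StudyTable(pd.concat([self.df, other.df], ignore_index=True))
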