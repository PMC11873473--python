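"""Entry-point-to-trochlear-groove (EPTG) angle from clicked landmarks.

The protocol records, on an anteroposterior view: (1) the lateral and
medial femoral condyles, (2) the apex of the distal trochlear notch,
(3) the lateral end of the medial ridge and the medial end of the lateral
ridge (where the ridges flatten out), and (4) optionally a transition
point, or an explicit "no visible transition point".

The EPTG is the angle at the notch apex between the line to the trochlear
entry point and the reference line perpendicular to the transcondylar
line.  The entry point is the transition point when one was marked,
otherwise the midpoint of the two ridge ends — the principal interpretive
decision of this implementation, configurable via ``entry_point``.
Angles are stored signed (positive = entry point lateral of the
reference); summaries conventionally report the magnitude.

Measurement sessions iterate over each knee twice — once with the
curvature maps shown and once without — in seeded random order, so raters
are blinded to the pairing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError

__all__ = [
    "LandmarkSet",
    "EPTGMeasurement",
    "SessionPlan",
    "MeasurementTable",
    "entry_point",
    "compute_eptg",
    "plan_session",
    "record_measurement",
    "load_landmarks",
]

NO_TRANSITION = "no visible transition point"


def _pt(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,) or not np.isfinite(a).all():
        raise ValidationError(f"landmark must be a finite 2D point, got {p!r}")
    return a


@dataclass
class LandmarkSet:
    """The clicked points of one EPTG measurement, in view coordinates.

    ``transition_point`` is either a 2D point or None, meaning the rater
    selected "there is no visible transition point".
    """

    lateral_condyle: np.ndarray
    medial_condyle: np.ndarray
    notch_apex: np.ndarray
    medial_ridge_end: np.ndarray
    lateral_ridge_end: np.ndarray
    transition_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lateral_condyle = _pt(self.lateral_condyle)
        self.medial_condyle = _pt(self.medial_condyle)
        self.notch_apex = _pt(self.notch_apex)
        self.medial_ridge_end = _pt(self.medial_ridge_end)
        self.lateral_ridge_end = _pt(self.lateral_ridge_end)
        if self.transition_point is not None:
            self.transition_point = _pt(self.transition_point)
        if np.allclose(self.lateral_condyle, self.medial_condyle):
            raise ValidationError("condyle landmarks coincide")
        if (np.allclose(self.notch_apex, self.medial_ridge_end)
                or np.allclose(self.notch_apex, self.lateral_ridge_end)):
            raise ValidationError("notch apex coincides with a ridge end")

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        tp = d.get("transition_point")
        if tp in (None, NO_TRANSITION, "none"):
            tp = None
        return cls(
            lateral_condyle=d["lateral_condyle"],
            medial_condyle=d["medial_condyle"],
            notch_apex=d["notch_apex"],
            medial_ridge_end=d["medial_ridge_end"],
            lateral_ridge_end=d["lateral_ridge_end"],
            transition_point=tp,
        )


def entry_point(landmarks: LandmarkSet) -> np.ndarray:
    """Trochlear entry point: the transition point if marked, otherwise
    the midpoint of the two ridge ends."""
    if landmarks.transition_point is not None:
        return landmarks.transition_point.copy()
    if np.allclose(landmarks.medial_ridge_end, landmarks.lateral_ridge_end):
        warnings.warn("ridge-end landmarks coincide; entry point degenerate",
                      stacklevel=2)
    return 0.5 * (landmarks.medial_ridge_end + landmarks.lateral_ridge_end)


def compute_eptg(landmarks: LandmarkSet) -> float:
    """Signed EPTG angle in degrees.

    The angle at the notch apex between the notch→entry-point line and the
    line through the notch perpendicular to the condyle-to-condyle line.
    Positive means the entry point lies on the lateral side of the
    reference line (the side of ``lateral_condyle``).  Invariant under
    rigid transforms and uniform scaling of the landmark set.
    """
    ep = entry_point(landmarks)
    t = landmarks.lateral_condyle - landmarks.medial_condyle
    tn = np.linalg.norm(t)
    if tn < 1e-12:
        raise GeometryError("condyle landmarks coincide")
    t_hat = t / tn  # medial → lateral
    v = ep - landmarks.notch_apex
    if np.linalg.norm(v) < 1e-12:
        raise GeometryError("entry point coincides with notch apex")
    lateral = float(v @ t_hat)
    along = float(np.sqrt(max(v @ v - lateral**2, 0.0)))  # |perp component|
    if along < 1e-12:
        raise GeometryError("entry point lies on the transcondylar line")
    return float(np.degrees(np.arctan2(lateral, along)))


@dataclass
class SessionPlan:
    """Randomized blinded measurement order: every knee twice, once per
    aid condition, in a seeded permutation."""

    items: list[tuple[str, bool]]
    seed: int
    completed: set = field(default_factory=set)

    def pending(self) -> list[tuple[str, bool]]:
        return [it for it in self.items if it not in self.completed]


def plan_session(knee_ids: list[str], seed: int) -> SessionPlan:
    """Build the randomized session: 2×len(knee_ids) items, seeded order."""
    if len(set(knee_ids)) != len(knee_ids):
        raise ValidationError("knee_ids must be unique")
    items = [(k, aid) for k in knee_ids for aid in (True, False)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    return SessionPlan(items=[items[i] for i in order], seed=seed)


@dataclass
class EPTGMeasurement:
    """One recorded EPTG measurement."""

    knee_id: str
    rater_id: str
    aid: bool
    repetition: int
    angle: float
    landmarks: LandmarkSet
    timestamp: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.angle) or abs(self.angle) >= 90:
            raise ValidationError(f"implausible EPTG angle: {self.angle}")
        if self.repetition < 1:
            raise ValidationError("repetition must be >= 1")


class MeasurementTable:
    """Accumulating table of EPTG measurements.

    Backed by a pandas DataFrame with columns knee_id, group, rater_id,
    aid, repetition, angle_deg, timestamp; (knee, rater, aid, repetition)
    keys are unique.
    """

    COLUMNS = ["knee_id", "group", "rater_id", "aid", "repetition",
               "angle_deg", "timestamp"]

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        self.df = df.reset_index(drop=True)
        self._check_keys()

    def _check_keys(self) -> None:
        keys = self.df[["knee_id", "rater_id", "aid", "repetition"]]
        dup = keys.duplicated()
        if dup.any():
            row = self.df[dup].iloc[0]
            raise ValidationError(
                "duplicate measurement key: "
                f"({row.knee_id}, {row.rater_id}, aid={row.aid}, "
                f"rep={row.repetition})"
            )

    def __len__(self) -> int:
        return len(self.df)

    def append(self, m: EPTGMeasurement, group: str | None = None) -> None:
        key = (m.knee_id, m.rater_id, m.aid, m.repetition)
        existing = set(map(tuple, self.df[
            ["knee_id", "rater_id", "aid", "repetition"]].itertuples(index=False)))
        if key in existing:
            raise ValidationError(f"measurement already recorded for {key}")
        row = {
            "knee_id": m.knee_id, "group": group, "rater_id": m.rater_id,
            "aid": m.aid, "repetition": m.repetition,
            "angle_deg": m.angle, "timestamp": m.timestamp,
        }
        self.df = pd.concat(
            [self.df, pd.DataFrame([row])], ignore_index=True
        ) if len(self.df) else pd.DataFrame([row], columns=self.COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementTable":
        df = pd.read_csv(path)
        missing = {"knee_id", "rater_id", "aid", "repetition", "angle_deg"} - set(df.columns)
        if missing:
            raise ValidationError(f"measurement CSV missing columns: {sorted(missing)}")
        if "group" not in df.columns:
            df["group"] = None
        if "timestamp" not in df.columns:
            df["timestamp"] = ""
        if df["aid"].dtype != bool:
            df["aid"] = df["aid"].astype(str).str.lower().isin(("true", "1", "yes"))
        return cls(df[cls.COLUMNS])

    def matrix(self, aid: bool, repetition: int = 1,
               raters: list[str] | None = None) -> pd.DataFrame:
        """Subjects × raters angle matrix for one condition/repetition."""
        sel = self.df[(self.df.aid == aid) & (self.df.repetition == repetition)]
        if raters is not None:
            sel = sel[sel.rater_id.isin(raters)]
        pivot = sel.pivot(index="knee_id", columns="rater_id",
                          values="angle_deg")
        if pivot.isna().any().any():
            raise ValidationError("incomplete subjects × raters matrix")
        return pivot.sort_index()

    def rater_matrix(self, rater_id: str, aid: bool) -> pd.DataFrame:
        """Subjects × repetitions matrix for one rater (intra-rater ICC)."""
        sel = self.df[(self.df.aid == aid) & (self.df.rater_id == rater_id)]
        pivot = sel.pivot(index="knee_id", columns="repetition",
                          values="angle_deg")
        if pivot.isna().any().any():
            raise ValidationError("incomplete subjects × repetitions matrix")
        return pivot.sort_index()


def record_measurement(plan: SessionPlan, knee_id: str, aid: bool,
                       landmarks: LandmarkSet, rater_id: str,
                       table: MeasurementTable, repetition: int = 1,
                       group: str | None = None,
                       timestamp: str | None = None) -> EPTGMeasurement:
    """Compute and persist one measurement for a pending plan item."""
    item = (knee_id, aid)
    if item not in plan.items:
        raise ValidationError(f"{item} is not in the session plan")
    if item in plan.completed:
        raise ValidationError(f"{item} was already measured in this session")
    angle = compute_eptg(landmarks)
    if timestamp is None:
        timestamp = datetime.now(timezone.utc).isoformat()
    m = EPTGMeasurement(knee_id=knee_id, rater_id=rater_id, aid=aid,
                        repetition=repetition, angle=angle,
                        landmarks=landmarks, timestamp=timestamp)
    table.append(m, group=group)
    plan.completed.add(item)
    return m


def load_landmarks(path: str | Path) -> dict[str, LandmarkSet]:
    """Read a batch landmark JSON file: {image_name: {landmark: [x, y]}}."""
    with open(path) as fh:
        raw = json.load(fh)
    return {name: LandmarkSet.from_dict(d) for name, d in raw.items()}
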