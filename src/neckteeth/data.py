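"""Domain records, tidy-table I/O, trait scoring, and landmark morphometry.

The unit of analysis is a single *Daphnia pulex* juvenile: its clonal
lineage, treatment assignment (kairomone yes/no, UVR yes/no), developmental
instar, maternal identity, and the measured defense and size traits
(neckteeth count 0-5, ordinal pedestal class A < B < C, and three lengths
in mm which may be missing when the photograph was unusable).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PEDESTAL_LEVELS",
    "PEDESTAL_TO_INT",
    "JuvenileRecord",
    "EffectivityRecord",
    "LandmarkSet",
    "InductionWeights",
    "SchemaError",
    "RecordValidationError",
    "make_mother_uid",
    "tollrian_induction_score",
    "landmark_lengths",
    "read_juvenile_table",
    "write_juvenile_table",
    "read_effectivity_table",
    "write_effectivity_table",
    "read_landmark_table",
    "write_landmark_table",
    "juveniles_to_frame",
    "frame_to_juveniles",
    "effectivity_to_frame",
    "frame_to_effectivity",
]

#: Ordered pedestal classes: A = absent, B = small, C = large.
PEDESTAL_LEVELS: tuple[str, ...] = ("A", "B", "C")
PEDESTAL_TO_INT: dict[str, int] = {"A": 1, "B": 2, "C": 3}

MAX_NECKTEETH = 5

JUVENILE_COLUMNS = [
    "clone",
    "kairomone",
    "uvr",
    "instar",
    "mother_uid",
    "neckteeth",
    "pedestal",
    "body_length_mm",
    "body_width_mm",
    "spina_length_mm",
    "survived_to_instar2",
]

EFFECTIVITY_COLUMNS = ["treatment", "exposure_hours", "mother_uid", "neckteeth", "pedestal"]

EFFECTIVITY_TREATMENTS = ("control", "PAR", "UVR")
EXPOSURE_HOURS = (2, 4, 6, 8)


class SchemaError(ValueError):
    """A table is missing a required column."""


class RecordValidationError(ValueError):
    """A row violates a record invariant; the message names the row."""


def make_mother_uid(clone: str, kairomone: bool, uvr: bool, mother_index: int) -> str:
    """Unique mother identifier over (clone, kairomone, uvr, index).

    Mothers are numbered consecutively within each clone-by-treatment cell,
    so the identifier must encode the full cell to be globally unique.
    """
    if mother_index < 1:
        raise ValueError(f"mother_index must be >= 1, got {mother_index}")
    return f"{clone}.K{int(bool(kairomone))}.U{int(bool(uvr))}.{int(mother_index)}"


def _validate_common(neckteeth: int, pedestal: str, where: str = "") -> None:
    if not 0 <= int(neckteeth) <= MAX_NECKTEETH:
        raise RecordValidationError(f"neckteeth must be in 0..{MAX_NECKTEETH}, got {neckteeth}{where}")
    if pedestal not in PEDESTAL_LEVELS:
        raise RecordValidationError(f"pedestal must be one of {PEDESTAL_LEVELS}, got {pedestal!r}{where}")


@dataclass(frozen=True)
class JuvenileRecord:
    """One juvenile from the main clone x kairomone x UVR experiment."""

    clone: str
    kairomone: bool
    uvr: bool
    instar: int
    mother_uid: str
    neckteeth: int
    pedestal: str
    body_length: float | None = None
    body_width: float | None = None
    spina_length: float | None = None
    survived_to_instar2: bool = True

    def __post_init__(self) -> None:
        _validate_common(self.neckteeth, self.pedestal)
        if self.instar not in (1, 2):
            raise RecordValidationError(f"instar must be 1 or 2, got {self.instar}")
        if self.instar == 2 and not self.survived_to_instar2:
            raise RecordValidationError("instar-2 record requires survived_to_instar2=True")
        for name in ("body_length", "body_width", "spina_length"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise RecordValidationError(f"{name} must be positive when present, got {v}")


@dataclass(frozen=True)
class EffectivityRecord:
    """One juvenile from the kairomone-effectivity trial (UNI clone).

    ``treatment`` refers to the light exposure of the kairomone *medium*
    before mothers were introduced; control jars carried no kairomone.
    """

    treatment: str
    exposure_hours: int
    mother_uid: str
    neckteeth: int
    pedestal: str

    def __post_init__(self) -> None:
        if self.treatment not in EFFECTIVITY_TREATMENTS:
            raise RecordValidationError(
                f"treatment must be one of {EFFECTIVITY_TREATMENTS}, got {self.treatment!r}"
            )
        if self.exposure_hours not in EXPOSURE_HOURS:
            raise RecordValidationError(
                f"exposure_hours must be one of {EXPOSURE_HOURS}, got {self.exposure_hours}"
            )
        _validate_common(self.neckteeth, self.pedestal)

    @property
    def kairomone(self) -> bool:
        return self.treatment != "control"


# ---------------------------------------------------------------------------
# Tollrian induction score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InductionWeights:
    """Weights combining pedestal class and neckteeth count into a 0-100% index.

    Defaults follow Tollrian's scoring scheme: 10% per necktooth (max five
    teeth) plus 0/30/50% for absent/small/large pedestal, capped at 100%.
    The weights are configuration, not data.
    """

    per_tooth_percent: float = 10.0
    pedestal_percent: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 30.0, "C": 50.0}
    )
    cap: float = 100.0

    def __post_init__(self) -> None:
        if self.per_tooth_percent < 0 or any(v < 0 for v in self.pedestal_percent.values()):
            raise ValueError("induction weights must be non-negative")
        single_max = max(self.per_tooth_percent * MAX_NECKTEETH, max(self.pedestal_percent.values()))
        if self.cap < single_max:
            raise ValueError(
                f"cap ({self.cap}) must be at least the largest single component ({single_max})"
            )


DEFAULT_INDUCTION_WEIGHTS = InductionWeights()


def tollrian_induction_score(
    neckteeth: int,
    pedestal: str,
    weights: InductionWeights = DEFAULT_INDUCTION_WEIGHTS,
) -> float:
    """Combined induction index in percent: pedestal weight + per-tooth weight, capped."""
    _validate_common(neckteeth, pedestal)
    raw = weights.pedestal_percent[pedestal] + weights.per_tooth_percent * int(neckteeth)
    return float(min(weights.cap, raw))


# ---------------------------------------------------------------------------
# Landmark morphometry
# ---------------------------------------------------------------------------

LANDMARK_NAMES = ("head_top", "spina_base", "spina_tip", "ventral_mid", "dorsal_mid")


@dataclass(frozen=True)
class LandmarkSet:
    """Labeled 2-D landmarks (mm) placed on a juvenile's photograph."""

    head_top: tuple[float, float]
    spina_base: tuple[float, float]
    spina_tip: tuple[float, float]
    ventral_mid: tuple[float, float]
    dorsal_mid: tuple[float, float]

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            pt = getattr(self, name)
            if pt is None:
                raise ValueError(f"missing landmark: {name}")
            if not all(math.isfinite(c) for c in pt):
                raise ValueError(f"non-finite coordinates for landmark {name}: {pt}")


def _dist(a: Sequence[float], b: Sequence[float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def landmark_lengths(landmarks: LandmarkSet) -> tuple[float, float, float]:
    """(body_length, body_width, spina_length) in mm from the landmark set.

    Body length is head top to tail-spine base, body width ventral to dorsal
    midpoint, spina length tail-spine base to tip.
    """
    body_length = _dist(landmarks.head_top, landmarks.spina_base)
    body_width = _dist(landmarks.ventral_mid, landmarks.dorsal_mid)
    spina_length = _dist(landmarks.spina_base, landmarks.spina_tip)
    return body_length, body_width, spina_length


# ---------------------------------------------------------------------------
# Tidy-table I/O
# ---------------------------------------------------------------------------

def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def _opt_len(value: float) -> float | None:
    return None if pd.isna(value) else float(value)


def juveniles_to_frame(records: Iterable[JuvenileRecord]) -> pd.DataFrame:
    rows = [
        {
            "clone": r.clone,
            "kairomone": int(r.kairomone),
            "uvr": int(r.uvr),
            "instar": r.instar,
            "mother_uid": r.mother_uid,
            "neckteeth": r.neckteeth,
            "pedestal": r.pedestal,
            "body_length_mm": np.nan if r.body_length is None else r.body_length,
            "body_width_mm": np.nan if r.body_width is None else r.body_width,
            "spina_length_mm": np.nan if r.spina_length is None else r.spina_length,
            "survived_to_instar2": int(r.survived_to_instar2),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=JUVENILE_COLUMNS)


def frame_to_juveniles(frame: pd.DataFrame) -> list[JuvenileRecord]:
    _require_columns(frame, JUVENILE_COLUMNS, "juvenile")
    records = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(
                JuvenileRecord(
                    clone=str(row["clone"]),
                    kairomone=bool(int(row["kairomone"])),
                    uvr=bool(int(row["uvr"])),
                    instar=int(row["instar"]),
                    mother_uid=str(row["mother_uid"]),
                    neckteeth=int(row["neckteeth"]),
                    pedestal=str(row["pedestal"]),
                    body_length=_opt_len(row["body_length_mm"]),
                    body_width=_opt_len(row["body_width_mm"]),
                    spina_length=_opt_len(row["spina_length_mm"]),
                    survived_to_instar2=bool(int(row["survived_to_instar2"])),
                )
            )
        except (RecordValidationError, ValueError) as exc:
            raise RecordValidationError(f"row {pos}: {exc}") from exc
    return records


def effectivity_to_frame(records: Iterable[EffectivityRecord]) -> pd.DataFrame:
    rows = [
        {
            "treatment": r.treatment,
            "exposure_hours": r.exposure_hours,
            "mother_uid": r.mother_uid,
            "neckteeth": r.neckteeth,
            "pedestal": r.pedestal,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=EFFECTIVITY_COLUMNS)


def frame_to_effectivity(frame: pd.DataFrame) -> list[EffectivityRecord]:
    _require_columns(frame, EFFECTIVITY_COLUMNS, "effectivity")
    records = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(
                EffectivityRecord(
                    treatment=str(row["treatment"]),
                    exposure_hours=int(row["exposure_hours"]),
                    mother_uid=str(row["mother_uid"]),
                    neckteeth=int(row["neckteeth"]),
                    pedestal=str(row["pedestal"]),
                )
            )
        except (RecordValidationError, ValueError) as exc:
            raise RecordValidationError(f"row {pos}: {exc}") from exc
    return records


def write_juvenile_table(records: Iterable[JuvenileRecord], path: str | Path) -> None:
    """Write juveniles.csv; missing lengths become empty cells, lengths %.6f."""
    juveniles_to_frame(records).to_csv(path, index=False, float_format="%.6f")


def read_juvenile_table(path: str | Path) -> list[JuvenileRecord]:
    frame = pd.read_csv(path, dtype={"clone": str, "mother_uid": str, "pedestal": str})
    return frame_to_juveniles(frame)


def read_landmark_table(path: str | Path) -> list[LandmarkSet]:
    """Read landmarks.csv: one juvenile per row, columns <name>_x / <name>_y
    for each named landmark, coordinates in mm."""
    frame = pd.read_csv(path)
    cols = [f"{n}_{ax}" for n in LANDMARK_NAMES for ax in ("x", "y")]
    _require_columns(frame, cols, "landmark")
    out = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        try:
            out.append(
                LandmarkSet(
                    **{
                        n: (float(row[f"{n}_x"]), float(row[f"{n}_y"]))
                        for n in LANDMARK_NAMES
                    }
                )
            )
        except ValueError as exc:
            raise RecordValidationError(f"row {pos}: {exc}") from exc
    return out


def write_landmark_table(landmarks: Iterable[LandmarkSet], path: str | Path) -> None:
    rows = []
    for lm in landmarks:
        row = {}
        for n in LANDMARK_NAMES:
            row[f"{n}_x"], row[f"{n}_y"] = getattr(lm, n)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def write_effectivity_table(records: Iterable[EffectivityRecord], path: str | Path) -> None:
    effectivity_to_frame(records).to_csv(path, index=False)


def read_effectivity_table(path: str | Path) -> list[EffectivityRecord]:
    frame = pd.read_csv(path, dtype={"treatment": str, "mother_uid": str, "pedestal": str})
    return frame_to_effectivity(frame)
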