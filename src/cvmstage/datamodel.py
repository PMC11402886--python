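"""Core containers shared by every pipeline stage.

The staging problem is read from three cervical vertebrae (C2, C3, C4) on a
lateral cephalogram.  Each radiograph is annotated with 19 numbered points in
image pixel coordinates (origin top-left, y increasing downward); a panel of
raters assigns each subject an ordinal maturation stage CS-1..CS-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

N_LANDMARKS = 19
STAGES = (1, 2, 3, 4, 5, 6)
SEXES = ("female", "male")

#: provenance tags of the five training datasets
PROVENANCES = ("Rater1", "Rater2", "Rater3", "MajorityVoting", "CompleteAgreement")


@dataclass(frozen=True)
class Landmark:
    """A single annotated point, pixel units, image y-axis pointing down."""

    id: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if not 1 <= self.id <= N_LANDMARKS:
            raise ValueError(f"landmark id {self.id} outside 1..{N_LANDMARKS}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"landmark {self.id}: non-finite coordinate")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"landmark {self.id}: negative coordinate")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class LandmarkSet:
    """All 19 points of one cephalogram."""

    subject_id: str
    landmarks: dict[int, Landmark]
    image_id: str = ""

    def __post_init__(self) -> None:
        ids = sorted(self.landmarks)
        if ids != list(range(1, N_LANDMARKS + 1)):
            missing = sorted(set(range(1, N_LANDMARKS + 1)) - set(ids))
            raise ValueError(
                f"{self.subject_id}: expected landmark ids 1..{N_LANDMARKS}, "
                f"missing {missing}" if missing else
                f"{self.subject_id}: unexpected landmark ids {ids}"
            )

    @classmethod
    def from_array(cls, subject_id: str, coords: np.ndarray,
                   image_id: str = "") -> "LandmarkSet":
        """Build from a (19, 2) array ordered by landmark id."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected shape (19, 2), got {coords.shape}")
        lms = {i + 1: Landmark(i + 1, float(x), float(y))
               for i, (x, y) in enumerate(coords)}
        return cls(subject_id=subject_id, landmarks=lms, image_id=image_id)

    def point(self, point_id: int) -> np.ndarray:
        return self.landmarks[point_id].xy

    def points(self, ids: Iterable[int]) -> np.ndarray:
        return np.array([self.landmarks[i].xy for i in ids])

    def to_array(self) -> np.ndarray:
        return self.points(range(1, N_LANDMARKS + 1))


@dataclass(frozen=True)
class Subject:
    """Demographics attached to one cephalogram."""

    subject_id: str
    age: float
    sex: str

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"{self.subject_id}: age must be positive")
        if self.sex not in SEXES:
            raise ValueError(f"{self.subject_id}: sex must be one of {SEXES}")


@dataclass
class RatingPanel:
    """Ordinal stage labels from one or more raters for a single subject.

    ``ratings`` holds the primary session; ``repeat_ratings`` the optional
    second session used for the intra-rater reliability study.
    """

    subject_id: str
    ratings: dict[str, int]
    repeat_ratings: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ratings:
            raise ValueError(f"{self.subject_id}: panel has no ratings")
        for session in (self.ratings, self.repeat_ratings):
            for rater, stage in session.items():
                if stage not in STAGES:
                    raise ValueError(
                        f"{self.subject_id}: rater {rater} stage {stage} "
                        f"outside 1..6")

    @property
    def raters(self) -> list[str]:
        return sorted(self.ratings)


@dataclass
class CohortTable:
    """Joined view of one cohort: demographics, landmarks, ratings, truth.

    ``true_stage`` is only populated for synthetic cohorts, where the
    generating stage is known; ingested clinical data carries no truth.
    """

    subjects: dict[str, Subject]
    landmark_sets: dict[str, LandmarkSet]
    panels: dict[str, RatingPanel]
    true_stage: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.panels:
            if sid not in self.landmark_sets:
                raise ValueError(f"rated subject {sid} has no landmarks")
            if sid not in self.subjects:
                raise ValueError(f"rated subject {sid} has no demographics")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


@dataclass
class LabeledDataset:
    """Feature matrix plus stage labels under one labelling provenance.

    ``X`` is indexed by subject_id with one named column per feature;
    ``y`` holds integer stages 1..6 aligned to ``X``.  ``split`` optionally
    tags each row 'train'/'test'.
    """

    provenance: str
    X: pd.DataFrame
    y: pd.Series
    split: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature matrix and labels are misaligned")
        if self.split is not None and not self.split.index.equals(self.X.index):
            raise ValueError("split column misaligned")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def stage_counts(self) -> pd.Series:
        """Subjects per stage, indexed 1..6 (zeros included)."""
        return self.y.value_counts().reindex(STAGES, fill_value=0)

    def subset(self, subject_ids: Iterable[str]) -> "LabeledDataset":
        ids = [s for s in subject_ids]
        return LabeledDataset(
            provenance=self.provenance,
            X=self.X.loc[ids],
            y=self.y.loc[ids],
            split=self.split.loc[ids] if self.split is not None else None,
        )


def sex_code(sex: str) -> int:
    """Numeric sex encoding used in feature vectors: female=1, male=0."""
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    return 1 if sex == "female" else 0


def panels_to_frame(panels: Mapping[str, RatingPanel]) -> pd.DataFrame:
    """Long-format view of a panel collection (one row per rating)."""
    rows = []
    for sid in sorted(panels):
        p = panels[sid]
        for rater, stage in sorted(p.ratings.items()):
            rows.append((sid, rater, stage, 1))
        for rater, stage in sorted(p.repeat_ratings.items()):
            rows.append((sid, rater, stage, 2))
    return pd.DataFrame(rows, columns=["subject_id", "rater_id", "stage", "session"])
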