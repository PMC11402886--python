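"""Readers and writers for the tabular and annotation formats the pipeline touches.

Formats (all UTF-8, comma-separated, decimal point):

* landmark CSV (long): ``subject_id,point_id,x,y`` — one row per point;
* ratings CSV: ``subject_id,rater_id,stage,session`` (session 1 = primary,
  2 = repeat);
* demographics CSV: ``subject_id,age,sex``;
* dataset CSV: one metadata comment line ``# provenance=...`` followed by a
  normal header and one row per subject;
* VGG Image Annotator (VIA) 2.x JSON exports with point regions.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    N_LANDMARKS,
    STAGES,
    Landmark,
    LandmarkSet,
    LabeledDataset,
    RatingPanel,
    Subject,
)


def read_landmark_csv(path: str | Path) -> list[LandmarkSet]:
    """Read a long-format landmark table into one LandmarkSet per subject.

    Row order is irrelevant; every subject must contribute exactly the ids
    1..19 once each.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "point_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.iloc[0]
            raise ValueError(
                f"{path}: non-numeric coordinate for subject "
                f"{row['subject_id']} point {row['point_id']}")
    sets = []
    for sid, grp in df.groupby("subject_id", sort=True):
        ids = grp["point_id"].astype(int)
        counts = ids.value_counts()
        dups = sorted(counts[counts > 1].index)
        if dups:
            raise ValueError(f"{sid} duplicate point {dups[0]}")
        missing = sorted(set(range(1, N_LANDMARKS + 1)) - set(ids))
        extra = sorted(set(ids) - set(range(1, N_LANDMARKS + 1)))
        if missing:
            raise ValueError(f"{sid} missing point {missing[0]}")
        if extra:
            raise ValueError(f"{sid} unexpected point {extra[0]}")
        lms = {
            int(r.point_id): Landmark(int(r.point_id), float(r.x), float(r.y))
            for r in grp.itertuples()
        }
        sets.append(LandmarkSet(subject_id=str(sid), landmarks=lms))
    return sets


def write_landmark_csv(sets: list[LandmarkSet], path: str | Path) -> None:
    rows = [
        (ls.subject_id, i, ls.landmarks[i].x, ls.landmarks[i].y)
        for ls in sets
        for i in range(1, N_LANDMARKS + 1)
    ]
    pd.DataFrame(rows, columns=["subject_id", "point_id", "x", "y"]).to_csv(
        path, index=False)


def read_via_json(path: str | Path, label_attr: str = "label",
                  subject_map: Mapping[str, str] | None = None,
                  ) -> list[LandmarkSet]:
    """Parse a VIA 2.x project/export JSON of point annotations.

    Point regions carry ``shape_attributes: {"name": "point", "cx":…, "cy":…}``
    and a region attribute named ``label_attr`` holding the landmark number
    "1".."19" (zero-padded accepted).  Non-point regions are skipped with a
    warning.  The filename stem is used as subject id unless ``subject_map``
    (filename → id) overrides it.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    # project files nest the image metadata under _via_img_metadata
    images = doc.get("_via_img_metadata", doc)
    sets = []
    for key in sorted(images):
        entry = images[key]
        fname = entry.get("filename", key)
        sid = (subject_map or {}).get(fname, Path(fname).stem)
        lms: dict[int, Landmark] = {}
        for region in entry.get("regions", []):
            shape = region.get("shape_attributes", {})
            if shape.get("name") != "point":
                warnings.warn(
                    f"{fname}: skipping non-point region "
                    f"{shape.get('name')!r}", stacklevel=2)
                continue
            raw = region.get("region_attributes", {}).get(label_attr)
            try:
                label = int(str(raw))
            except (TypeError, ValueError):
                raise ValueError(f"{fname}: unparseable point label {raw!r}")
            if not 1 <= label <= N_LANDMARKS:
                raise ValueError(f"{fname}: point label {label} outside 1..19")
            if label in lms:
                raise ValueError(f"{fname}: duplicate point label {label}")
            lms[label] = Landmark(label, float(shape["cx"]), float(shape["cy"]))
        sets.append(LandmarkSet(subject_id=sid, landmarks=lms, image_id=fname))
    return sets


def read_ratings_csv(path: str | Path) -> list[RatingPanel]:
    """Read rater stage labels; session 1 fills ratings, 2 fills repeats."""
    df = pd.read_csv(path, dtype={"subject_id": str, "rater_id": str})
    required = {"subject_id", "rater_id", "stage", "session"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = df[~df["stage"].isin(STAGES)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: stage {row['stage']} outside 1..6 "
            f"(subject {row['subject_id']}, rater {row['rater_id']})")
    dup = df.duplicated(["subject_id", "rater_id", "session"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate rating for subject {row['subject_id']}, "
            f"rater {row['rater_id']}, session {row['session']}")
    panels = []
    for sid, grp in df.groupby("subject_id", sort=True):
        primary = {str(r.rater_id): int(r.stage)
                   for r in grp.itertuples() if int(r.session) == 1}
        repeat = {str(r.rater_id): int(r.stage)
                  for r in grp.itertuples() if int(r.session) == 2}
        panels.append(RatingPanel(subject_id=str(sid), ratings=primary,
                                  repeat_ratings=repeat))
    return panels


def write_ratings_csv(panels: list[RatingPanel], path: str | Path) -> None:
    from .datamodel import panels_to_frame
    panels_to_frame({p.subject_id: p for p in panels}).to_csv(path, index=False)


def read_demographics_csv(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "age", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [Subject(str(r.subject_id), float(r.age), str(r.sex))
            for r in df.itertuples()]


def write_demographics_csv(subjects: list[Subject], path: str | Path) -> None:
    pd.DataFrame(
        [(s.subject_id, s.age, s.sex) for s in subjects],
        columns=["subject_id", "age", "sex"],
    ).to_csv(path, index=False)


def write_dataset_csv(dataset: LabeledDataset, path: str | Path,
                      overwrite: bool = False) -> None:
    """Write a labelled dataset with its provenance on a metadata line."""
    path = Path(path)
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True)")
    df = dataset.X.copy()
    df["stage"] = dataset.y
    if dataset.split is not None:
        df["split"] = dataset.split
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# provenance={dataset.provenance}\n")
        df.to_csv(fh, index=True, index_label="subject_id")


def read_dataset_csv(path: str | Path) -> LabeledDataset:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first.startswith("# provenance="):
        raise ValueError(f"{path}: missing provenance metadata line")
    provenance = first.split("=", 1)[1]
    df = pd.read_csv(path, comment="#", index_col="subject_id")
    df.index = df.index.astype(str)
    split = None
    if "split" in df.columns:
        split = df.pop("split")
    y = df.pop("stage").astype(int)
    return LabeledDataset(provenance=provenance, X=df, y=y, split=split)
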