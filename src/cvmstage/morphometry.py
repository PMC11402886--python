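"""Geometric features of the cervical vertebrae C2-C4.

The maturation signal is carried by two morphological trends: the inferior
border of each vertebral body develops a progressively deeper concavity, and
the C3/C4 bodies change shape from trapezoidal through horizontally
rectangular and square to vertically rectangular.  Both are quantified from
the 19 annotated points:

* concavity — the vertex angle at the deepest interior point, the
  perpendicular height of that point above the corner-to-corner chord, and
  the area enclosed between the border polyline and the chord (``AUC``);
* body shape — horizontal/vertical (h/v) ratios of the inferior-border width
  over the posterior and anterior edge heights;
* plus raw widths/heights, chronological age, and sex.

All geometry is computed in image pixel coordinates (origin top-left,
y pointing down); every feature is invariant under rigid motion of the
landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .datamodel import LandmarkSet, Subject, sex_code

Point = np.ndarray


@dataclass(frozen=True)
class VertebraScheme:
    """Role assignment of the landmark ids belonging to one vertebra.

    ``inferior_border`` runs posterior corner → interior points → anterior
    corner; ``deepest`` is the interior point at the bottom of the concavity.
    C2 is annotated on its inferior border only; C3/C4 additionally carry
    posterior-superior and anterior-superior corner points.
    """

    name: str
    inferior_border: tuple[int, ...]
    deepest: int
    superior_posterior: int | None = None
    superior_anterior: int | None = None

    def __post_init__(self) -> None:
        if len(self.inferior_border) < 3:
            raise ValueError(f"{self.name}: inferior border needs >=3 points")
        if self.deepest not in self.inferior_border[1:-1]:
            raise ValueError(f"{self.name}: deepest point must be interior")

    @property
    def corners(self) -> tuple[int, int]:
        return self.inferior_border[0], self.inferior_border[-1]

    @property
    def point_ids(self) -> tuple[int, ...]:
        ids = list(self.inferior_border)
        for extra in (self.superior_posterior, self.superior_anterior):
            if extra is not None:
                ids.append(extra)
        return tuple(ids)


@dataclass(frozen=True)
class LandmarkScheme:
    """The full 19-point role map across C2, C3, C4."""

    vertebrae: tuple[VertebraScheme, ...]

    def __post_init__(self) -> None:
        ids = [i for v in self.vertebrae for i in v.point_ids]
        if sorted(ids) != list(range(1, 20)):
            raise ValueError(f"scheme must cover ids 1..19 exactly once, got {sorted(ids)}")

    def vertebra(self, name: str) -> VertebraScheme:
        for v in self.vertebrae:
            if v.name == name:
                return v
        raise KeyError(name)

    @classmethod
    def from_yaml(cls, path: str) -> "LandmarkScheme":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(tuple(
            VertebraScheme(
                name=v["name"],
                inferior_border=tuple(v["inferior_border"]),
                deepest=v["deepest"],
                superior_posterior=v.get("superior_posterior"),
                superior_anterior=v.get("superior_anterior"),
            )
            for v in doc["vertebrae"]
        ))

    def to_yaml(self, path: str) -> None:
        doc = {"vertebrae": [
            {
                "name": v.name,
                "inferior_border": list(v.inferior_border),
                "deepest": v.deepest,
                "superior_posterior": v.superior_posterior,
                "superior_anterior": v.superior_anterior,
            }
            for v in self.vertebrae
        ]}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


#: default role map: 5 points along the C2 inferior border, 7 per C3/C4 body
DEFAULT_SCHEME = LandmarkScheme((
    VertebraScheme("C2", (1, 2, 3, 4, 5), deepest=3),
    VertebraScheme("C3", (6, 7, 8, 9, 10), deepest=8,
                   superior_posterior=11, superior_anterior=12),
    VertebraScheme("C4", (13, 14, 15, 16, 17), deepest=15,
                   superior_posterior=18, superior_anterior=19),
))


# ---------------------------------------------------------------- primitives

def vertex_angle(a: Point, v: Point, b: Point) -> float:
    """Angle at vertex ``v`` subtended by ``a`` and ``b``, in degrees (0, 180]."""
    a, v, b = (np.asarray(p, dtype=float) for p in (a, v, b))
    u1, u2 = a - v, b - v
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate angle: zero-length arm")
    cosang = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def chord_height(p: Point, c1: Point, c2: Point) -> float:
    """Perpendicular distance from ``p`` to the infinite line through c1, c2."""
    p, c1, c2 = (np.asarray(q, dtype=float) for q in (p, c1, c2))
    chord = c2 - c1
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValueError("degenerate chord: identical endpoints")
    rel = p - c1
    cross = chord[0] * rel[1] - chord[1] * rel[0]
    return float(abs(cross) / norm)


def concavity_auc(border: Sequence[Point]) -> float:
    """Area between a border polyline and its corner-to-corner chord.

    Absolute shoelace area of the closed polygon formed by the border points
    and the chord back from the last corner to the first; orientation
    invariant, zero when all points are collinear.
    """
    pts = np.asarray(border, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("border needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def point_distance(a: Point, b: Point) -> float:
    """Euclidean distance in pixels."""
    return float(np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def hv_ratio(width_pts: tuple[Point, Point], height_pts: tuple[Point, Point]) -> float:
    """Horizontal-over-vertical body shape ratio.

    >1 horizontally rectangular, 1 square, <1 vertically rectangular.  The
    "right" variant divides the inferior width by the posterior edge height,
    the "left" variant by the anterior edge height.
    """
    h = point_distance(*height_pts)
    if h == 0:
        raise ValueError("zero height in h/v ratio")
    return point_distance(*width_pts) / h


# ----------------------------------------------------------- feature vector

def feature_names(scheme: LandmarkScheme = DEFAULT_SCHEME) -> list[str]:
    """Stable ordered names of the full candidate feature set."""
    names: list[str] = []
    for v in scheme.vertebrae:
        c1, c2 = v.corners
        names.append(f"{v.name}_angle_{c1}_{v.deepest}_{c2}")
        names.append(f"{v.name}_height_{c1}_{v.deepest}_{c2}")
        names.append(f"{v.name}_AUC")
        names.append(f"{v.name}_width_{c1}_{c2}")
        if v.superior_posterior is not None:
            sp, sa = v.superior_posterior, v.superior_anterior
            names.append(f"{v.name}_width_sup_{sp}_{sa}")
            names.append(f"{v.name}_height_post_{c1}_{sp}")
            names.append(f"{v.name}_height_ant_{c2}_{sa}")
            names.append(f"{v.name}_ratio_hv_right")
            names.append(f"{v.name}_ratio_hv_left")
    names.extend(["age", "sex"])
    return names


def extract_features(ls: LandmarkSet, subj: Subject,
                     scheme: LandmarkScheme = DEFAULT_SCHEME,
                     normalize_lengths: bool = False) -> dict[str, float]:
    """Compute every candidate feature for one subject.

    With ``normalize_lengths`` the pixel-valued features (heights, widths,
    AUC) are divided by the C3 inferior-border width (AUC by its square),
    removing the unknown image scale; off by default since the raw pixel
    coordinates are what the annotation tool exports.
    """
    feats: dict[str, float] = {}
    try:
        for v in scheme.vertebrae:
            c1, c2 = v.corners
            p1, p2 = ls.point(c1), ls.point(c2)
            deep = ls.point(v.deepest)
            border = ls.points(v.inferior_border)
            feats[f"{v.name}_angle_{c1}_{v.deepest}_{c2}"] = vertex_angle(p1, deep, p2)
            feats[f"{v.name}_height_{c1}_{v.deepest}_{c2}"] = chord_height(deep, p1, p2)
            feats[f"{v.name}_AUC"] = concavity_auc(border)
            feats[f"{v.name}_width_{c1}_{c2}"] = point_distance(p1, p2)
            if v.superior_posterior is not None:
                sp, sa = v.superior_posterior, v.superior_anterior
                psup, asup = ls.point(sp), ls.point(sa)
                feats[f"{v.name}_width_sup_{sp}_{sa}"] = point_distance(psup, asup)
                feats[f"{v.name}_height_post_{c1}_{sp}"] = point_distance(p1, psup)
                feats[f"{v.name}_height_ant_{c2}_{sa}"] = point_distance(p2, asup)
                feats[f"{v.name}_ratio_hv_right"] = hv_ratio((p1, p2), (p1, psup))
                feats[f"{v.name}_ratio_hv_left"] = hv_ratio((p1, p2), (p2, asup))
    except ValueError as exc:
        raise ValueError(f"subject {ls.subject_id}: {exc}") from exc
    if normalize_lengths:
        ref = feats["C3_width_6_10"]
        for name in list(feats):
            if "_height" in name or "_width" in name:
                feats[name] /= ref
            elif name.endswith("_AUC"):
                feats[name] /= ref**2
    feats["age"] = float(subj.age)
    feats["sex"] = float(sex_code(subj.sex))
    return feats


def extract_feature_table(landmark_sets: Sequence[LandmarkSet],
                          subjects: Sequence[Subject],
                          scheme: LandmarkScheme = DEFAULT_SCHEME,
                          normalize_lengths: bool = False):
    """Feature matrix for a cohort, indexed by subject_id."""
    import pandas as pd

    by_id = {s.subject_id: s for s in subjects}
    rows, index = [], []
    for ls in landmark_sets:
        if ls.subject_id not in by_id:
            raise ValueError(f"no demographics for subject {ls.subject_id}")
        rows.append(extract_features(ls, by_id[ls.subject_id], scheme,
                                     normalize_lengths))
        index.append(ls.subject_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"),
                        columns=feature_names(scheme))
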