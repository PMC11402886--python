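"""Inter-/intra-rater agreement and consensus label construction.

Agreement on the ordinal six-stage scale is measured with weighted kappa,
which discounts chance agreement and penalizes disagreements by their
ordinal distance.  A three-rater panel is partitioned per subject into
Complete Agreement (all three equal), Partial Agreement (exactly two equal)
and Disagreement (all distinct, excluded from consensus labelling); the
Majority Voting set is the union of the first two, labelled with the modal
rating.  Five training datasets result: one per rater plus the two
consensus-based ones.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    LabeledDataset,
    PROVENANCES,
    RatingPanel,
    STAGES,
)

_SCHEMES = ("linear", "quadratic")

#: package-wide default disagreement weighting for the six-stage scale
DEFAULT_WEIGHT_SCHEME = "linear"


def _weight_matrix(k: int, scheme: str) -> np.ndarray:
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}")
    d = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    return d if scheme == "linear" else d**2


def weighted_kappa(a, b, scheme: str = DEFAULT_WEIGHT_SCHEME,
                   k: int = 6) -> float:
    """Weighted Cohen's kappa for two aligned ordinal label sequences.

    kappa = 1 - sum(w * O) / sum(w * E), with O the joint proportion table,
    E the outer product of the two marginals, and disagreement weights
    w_ij = |i-j|/(k-1) (linear) or its square (quadratic).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two rated subjects")
    if a.min() < 1 or a.max() > k or b.min() < 1 or b.max() > k:
        raise ValueError(f"labels outside 1..{k}")
    w = _weight_matrix(k, scheme)
    obs = np.zeros((k, k))
    np.add.at(obs, (a - 1, b - 1), 1.0)
    obs /= len(a)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    denom = float((w * expected).sum())
    if denom == 0.0:
        # both raters constant and equal: no chance disagreement to correct
        warnings.warn("zero expected disagreement; kappa defined as 1.0",
                      stacklevel=2)
        return 1.0
    return float(1.0 - (w * obs).sum() / denom)


def kappa_ci(a, b, scheme: str = DEFAULT_WEIGHT_SCHEME, k: int = 6,
             n_boot: int = 2000,
             rng: np.random.Generator | int | None = None,
             ) -> tuple[float, float, float, float]:
    """Weighted kappa with nonparametric bootstrap 95% CI and SD.

    Resamples subjects with replacement; returns (kappa, ci_low, ci_high,
    sd) with the percentile 2.5/97.5 interval and the SD of the bootstrap
    replicates.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    point = weighted_kappa(a, b, scheme=scheme, k=k)
    rng = np.random.default_rng(rng)
    n = len(a)
    reps = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            reps[i] = weighted_kappa(a[idx], b[idx], scheme=scheme, k=k)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, float(lo), float(hi), float(reps.std(ddof=1))


@dataclass
class AgreementReport:
    """Pairwise inter-rater and per-rater intra-rater weighted kappas."""

    inter: dict[tuple[str, str], tuple[float, float, float, float]]
    intra: dict[str, tuple[float, float, float, float]]
    scheme: str = DEFAULT_WEIGHT_SCHEME

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (r1, r2), (kap, lo, hi, sd) in sorted(self.inter.items()):
            rows.append(("inter", f"{r1} vs {r2}", kap, lo, hi, sd))
        for rater, (kap, lo, hi, sd) in sorted(self.intra.items()):
            rows.append(("intra", rater, kap, lo, hi, sd))
        return pd.DataFrame(
            rows, columns=["kind", "raters", "weighted_kappa",
                           "ci_low", "ci_high", "sd"])


def agreement_report(panels: list[RatingPanel],
                     scheme: str = DEFAULT_WEIGHT_SCHEME,
                     n_boot: int = 2000,
                     rng: np.random.Generator | int | None = None,
                     ) -> AgreementReport:
    """Compute all pairwise inter- and per-rater intra-rater kappas."""
    rng = np.random.default_rng(rng)
    raters = sorted({r for p in panels for r in p.ratings})
    inter = {}
    for i, r1 in enumerate(raters):
        for r2 in raters[i + 1:]:
            sids = [p for p in panels if r1 in p.ratings and r2 in p.ratings]
            a = [p.ratings[r1] for p in sids]
            b = [p.ratings[r2] for p in sids]
            inter[(r1, r2)] = kappa_ci(a, b, scheme=scheme, n_boot=n_boot,
                                       rng=rng)
    intra = {}
    for r in raters:
        both = [p for p in panels if r in p.ratings and r in p.repeat_ratings]
        if len(both) >= 2:
            a = [p.ratings[r] for p in both]
            b = [p.repeat_ratings[r] for p in both]
            intra[r] = kappa_ci(a, b, scheme=scheme, n_boot=n_boot, rng=rng)
    return AgreementReport(inter=inter, intra=intra, scheme=scheme)


# ------------------------------------------------------------- consensus

CATEGORIES = ("Complete", "Partial", "Disagreement")


@dataclass
class ConsensusPartition:
    """Per-subject consensus category and modal label (three-rater panels).

    Complete: all three raters equal; Partial: exactly two equal;
    Disagreement: all distinct — such subjects carry no consensus label and
    are excluded from the consensus datasets.
    """

    category: dict[str, str]
    consensus: dict[str, int] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        c = Counter(self.category.values())
        return {cat: c.get(cat, 0) for cat in CATEGORIES}

    def summary(self) -> dict[str, float]:
        """Category counts plus the derived fractions (percent scale)."""
        c = self.counts()
        n = sum(c.values())
        mv = c["Complete"] + c["Partial"]
        return {
            "n": n,
            "complete": c["Complete"],
            "partial": c["Partial"],
            "disagreement": c["Disagreement"],
            "majority_voting": mv,
            "complete_pct": 100.0 * c["Complete"] / n,
            "partial_pct": 100.0 * c["Partial"] / n,
            "majority_voting_pct": 100.0 * mv / n,
            "disagreement_pct": 100.0 * c["Disagreement"] / n,
        }

    def members(self, category: str) -> list[str]:
        return sorted(s for s, c in self.category.items() if c == category)


def consensus_partition(panels: list[RatingPanel]) -> ConsensusPartition:
    """Partition three-rater panels into Complete/Partial/Disagreement."""
    category: dict[str, str] = {}
    consensus: dict[str, int] = {}
    for p in panels:
        if len(p.ratings) != 3:
            raise ValueError(
                f"{p.subject_id}: consensus partition requires exactly 3 "
                f"raters, got {len(p.ratings)}")
        votes = Counter(p.ratings.values())
        top_label, top_n = votes.most_common(1)[0]
        if top_n == 3:
            category[p.subject_id] = "Complete"
            consensus[p.subject_id] = top_label
        elif top_n == 2:
            category[p.subject_id] = "Partial"
            consensus[p.subject_id] = top_label
        else:
            category[p.subject_id] = "Disagreement"
    return ConsensusPartition(category=category, consensus=consensus)


def build_datasets(features: pd.DataFrame, panels: list[RatingPanel],
                   partition: ConsensusPartition | None = None,
                   ) -> dict[str, LabeledDataset]:
    """Assemble the five training datasets from features and ratings.

    Rater-k datasets label every rated subject with that rater's primary
    rating; MajorityVoting covers Complete ∪ Partial subjects with the
    modal label; CompleteAgreement its unanimous subset.  Subjects with
    features but no ratings are dropped with a warning.
    """
    panels = sorted(panels, key=lambda p: p.subject_id)
    rated = [p for p in panels if p.subject_id in features.index]
    unrated_features = set(features.index) - {p.subject_id for p in panels}
    if unrated_features:
        warnings.warn(
            f"{len(unrated_features)} subjects have features but no "
            f"ratings; excluded", stacklevel=2)
    missing_features = [p.subject_id for p in panels
                        if p.subject_id not in features.index]
    if missing_features:
        raise ValueError(
            f"{len(missing_features)} rated subjects lack features, "
            f"e.g. {missing_features[0]}")
    if partition is None:
        partition = consensus_partition(rated)

    raters = sorted({r for p in rated for r in p.ratings})
    if len(raters) != 3:
        raise ValueError(f"expected 3 raters, found {raters}")

    datasets: dict[str, LabeledDataset] = {}
    for i, rater in enumerate(raters, start=1):
        ids = [p.subject_id for p in rated]
        y = pd.Series([p.ratings[rater] for p in rated], index=ids, name="stage")
        datasets[f"Rater{i}"] = LabeledDataset(
            provenance=f"Rater{i}", X=features.loc[ids], y=y)
    for provenance, cats in (("MajorityVoting", ("Complete", "Partial")),
                             ("CompleteAgreement", ("Complete",))):
        ids = sorted(s for cat in cats for s in partition.members(cat)
                     if s in features.index)
        y = pd.Series([partition.consensus[s] for s in ids], index=ids,
                      name="stage")
        datasets[provenance] = LabeledDataset(
            provenance=provenance, X=features.loc[ids], y=y)
    assert set(datasets) == set(PROVENANCES)
    return datasets


def stage_count_table(datasets: dict[str, LabeledDataset]) -> pd.DataFrame:
    """Per-stage subject counts of each dataset (rows CS-1..CS-6 + total)."""
    tab = pd.DataFrame({name: ds.stage_counts()
                        for name, ds in datasets.items()})
    tab.index = [f"CS-{s}" for s in STAGES]
    tab.loc["Total"] = tab.sum()
    return tab
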