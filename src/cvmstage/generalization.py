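"""Cross-dataset generalization of the per-dataset top models.

Each dataset contributes a stratified 30% holdout; every top model is then
scored on the four holdouts it was not trained from.  Per model, the four
accuracies are summarized by mean, sample SD (n-1) and coefficient of
variation CV = SD/mean; models are ranked by ascending CV — a lower CV
means more consistent performance across labelling provenances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import LabeledDataset, STAGES
from .modeling import TrainedModel
from sklearn.metrics import accuracy_score


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample SD and CV of an accuracy list (proportion scale)."""

    mean: float
    sd: float
    cv: float
    n: int

    def formatted(self) -> dict[str, str]:
        """Report convention: mean as a percentage with one decimal, SD and
        CV on the proportion scale at two decimals."""
        return {
            "mean": f"{100 * self.mean:.1f}%",
            "sd": f"{self.sd:.2f}",
            "cv": f"{self.cv:.2f}",
        }


def summarize(accs) -> SummaryStats:
    """Summary statistics of cross-dataset accuracies.

    Uses the sample (n-1) standard deviation; requires at least two values
    and a positive mean (CV is undefined otherwise).
    """
    a = np.asarray(list(accs), dtype=float)
    if len(a) < 2:
        raise ValueError("need at least two accuracies")
    mean = float(a.mean())
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean accuracy")
    sd = float(a.std(ddof=1))
    return SummaryStats(mean=mean, sd=sd, cv=sd / mean, n=len(a))


@dataclass
class HoldoutSet:
    """A stratified 30% sample of one dataset, used as an unseen test set."""

    provenance: str
    data: LabeledDataset
    seed: int

    def stage_counts(self) -> pd.Series:
        return self.data.stage_counts()

    def __len__(self) -> int:
        return len(self.data)


def make_holdouts(datasets: dict[str, LabeledDataset], frac: float = 0.30,
                  seed: int = 0) -> dict[str, HoldoutSet]:
    """Per-stage stratified samples preserving each dataset's distribution.

    Stage shares are allocated by largest remainder, so the total equals
    ``round(frac * n)`` and each stage is within one subject of ``frac``
    of its size; a stage with no members simply contributes none.
    """
    rng = np.random.default_rng(seed)
    holdouts = {}
    for name in sorted(datasets):
        ds = datasets[name]
        counts = ds.stage_counts().to_numpy()
        target = counts * frac
        floor = np.floor(target).astype(int)
        short = int(round(target.sum())) - int(floor.sum())
        order = np.argsort(-(target - floor), kind="stable")
        draw = floor.copy()
        draw[order[:short]] += 1
        ids: list[str] = []
        for stage, k in zip(STAGES, draw):
            members = np.array(sorted(ds.y.index[ds.y == stage]))
            if len(members) == 0:
                continue
            pick = rng.choice(len(members), size=int(k), replace=False)
            ids.extend(members[np.sort(pick)])
        holdouts[name] = HoldoutSet(provenance=name,
                                    data=ds.subset(sorted(ids)), seed=seed)
    return holdouts


@dataclass
class GeneralizationReport:
    """Model x unseen-dataset accuracy matrix with per-model summaries.

    ``matrix`` has one column per model provenance and one row per holdout
    provenance; diagonal cells (own dataset) are NaN.  ``excluded`` counts
    holdout subjects dropped per cell because they were in that model's
    training split (preserving 'unseen' semantics).
    """

    matrix: pd.DataFrame
    summaries: dict[str, SummaryStats]
    excluded: pd.DataFrame

    def ranking(self) -> list[str]:
        """Model provenances by ascending CV (ties by name)."""
        return sorted(self.summaries, key=lambda m: (self.summaries[m].cv, m))

    def to_frame(self) -> pd.DataFrame:
        """Table with the accuracy matrix plus mean/SD/CV summary rows."""
        out = (100 * self.matrix).round(1)
        out.loc["Average accuracy"] = [
            round(100 * self.summaries[c].mean, 1) for c in out.columns]
        out.loc["SD"] = [round(self.summaries[c].sd, 2) for c in out.columns]
        out.loc["CV"] = [round(self.summaries[c].cv, 2) for c in out.columns]
        return out


def cross_evaluate(top_models: dict[str, TrainedModel],
                   holdouts: dict[str, HoldoutSet]) -> GeneralizationReport:
    """Score each top model on the four holdouts of other provenances.

    Any holdout subject that was in a model's own training split is
    excluded from that cell before scoring, and counted in ``excluded``.
    """
    names = sorted(top_models)
    if set(names) != set(holdouts):
        raise ValueError("models and holdouts must cover the same provenances")
    matrix = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    excluded = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for model_name in names:
        model = top_models[model_name]
        train_ids = set(model.train_ids)
        for holdout_name in names:
            if holdout_name == model_name:
                continue
            data = holdouts[holdout_name].data
            keep = [s for s in data.X.index if s not in train_ids]
            excluded.loc[holdout_name, model_name] = len(data) - len(keep)
            if not keep:
                raise ValueError(
                    f"holdout {holdout_name} fully overlaps training of "
                    f"{model_name}")
            sub = data.subset(keep)
            pred = model.predict(sub.X)
            matrix.loc[holdout_name, model_name] = float(
                accuracy_score(sub.y.to_numpy(), pred))
    summaries = {m: summarize(matrix[m].dropna()) for m in names}
    return GeneralizationReport(matrix=matrix, summaries=summaries,
                                excluded=excluded)
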