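"""End-to-end study orchestration.

Two entry points:

* :func:`run_replicate` — one in-memory replicate of the whole study
  (simulate → features → agreement → consensus → five datasets → per-dataset
  model selection → cross-dataset generalization), used by tests and the
  acceptance script;
* :func:`run_pipeline` — the same stages driven by a :class:`RunConfig`,
  writing every intermediate as plain CSV/JSON into a run directory so any
  report number can be recomputed from files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import cohort as coh
from . import generalization as gen
from . import io as cio
from . import modeling as mod
from .datamodel import LabeledDataset, PROVENANCES
from .morphometry import extract_feature_table

log = logging.getLogger("cvmstage")

#: reliability targets the simulated panel is calibrated to
INTER_KAPPA_RANGE = (0.62, 0.78)
INTRA_KAPPA_RANGE = (0.86, 0.92)


@dataclass
class RunConfig:
    """Knobs of one pipeline run; round-trips to YAML."""

    seed: int = 0
    outdir: str = "runs/run0"
    size_factor: float = 1.0
    jitter_sd: float = 1.5
    n_repeat: int = 35
    calibration_n_sim: int = 2000
    kappa_n_boot: int = 500
    search_budget: int = 50
    cv_folds: int = 5
    selection_trees: int = 300
    families: tuple[str, ...] = mod.FAMILIES
    holdout_frac: float = 0.30
    morphology_yaml: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["families"] = list(self.families)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        doc["families"] = tuple(doc.get("families", mod.FAMILIES))
        return cls(**doc)


@dataclass
class ReplicateResult:
    """All study outputs of one seed."""

    seed: int
    profiles: list[coh.RaterProfile]
    calibration: dict[str, float]
    cohort: object
    features: pd.DataFrame
    partition: agr.ConsensusPartition
    datasets: dict[str, LabeledDataset]
    selections: dict[str, mod.SelectionReport] = field(default_factory=dict)
    reports: dict[str, list[mod.ModelReport]] = field(default_factory=dict)
    top: dict[str, mod.ModelReport] = field(default_factory=dict)
    generalization: gen.GeneralizationReport | None = None

    def accuracy_table(self) -> pd.DataFrame:
        """Family x provenance test-accuracy table (proportion scale)."""
        tab = pd.DataFrame({
            prov: {r.family: r.test_accuracy for r in reps}
            for prov, reps in self.reports.items()
        })
        rows = [f for f in mod.FAMILIES if f in tab.index]
        return tab.loc[rows, list(PROVENANCES)]


def run_replicate(seed: int, size_factor: float = 1.0,
                  search_budget: int = 50, cv_folds: int = 5,
                  families=mod.FAMILIES, jitter_sd: float = 1.5,
                  calibration_n_sim: int = 2000, selection_trees: int = 300,
                  holdout_frac: float = 0.30,
                  profiles: list[coh.RaterProfile] | None = None,
                  with_models: bool = True) -> ReplicateResult:
    """Run one full synthetic replicate of the study.

    Seeds for the calibration, cohort, splits, searches and holdouts are
    all derived from ``seed``.  ``with_models=False`` stops after dataset
    construction (cheap, for agreement-only studies).
    """
    rng = np.random.default_rng(seed)
    if profiles is None:
        profiles, calibration = coh.calibrate_profiles(
            INTER_KAPPA_RANGE, INTRA_KAPPA_RANGE, n_sim=calibration_n_sim,
            rng=rng)
    else:
        calibration = {}
    spec = coh.CohortSpec(jitter_sd=jitter_sd, seed=int(rng.integers(2**31)),
                          n_repeat=35).scaled(size_factor)
    cohort = coh.generate_cohort(spec, profiles=profiles)
    subjects = [cohort.subjects[s] for s in cohort.subject_ids]
    lsets = [cohort.landmark_sets[s] for s in cohort.subject_ids]
    features = extract_feature_table(lsets, subjects)
    panels = [cohort.panels[s] for s in sorted(cohort.panels)]
    partition = agr.consensus_partition(panels)
    datasets = agr.build_datasets(features, panels, partition)

    result = ReplicateResult(
        seed=seed, profiles=profiles, calibration=calibration, cohort=cohort,
        features=features, partition=partition, datasets=datasets)
    if not with_models:
        return result

    model_seed = int(rng.integers(2**31))
    for prov in PROVENANCES:
        top, reports, selection = mod.train_dataset(
            datasets[prov], families=families, search_budget=search_budget,
            cv_folds=cv_folds, seed=model_seed, n_trees=selection_trees)
        result.selections[prov] = selection
        result.reports[prov] = reports
        result.top[prov] = top
    holdouts = gen.make_holdouts(datasets, frac=holdout_frac,
                                 seed=int(rng.integers(2**31)))
    result.generalization = gen.cross_evaluate(
        {p: result.top[p].model for p in PROVENANCES}, holdouts)
    return result


# ----------------------------------------------------------------- run dir

STAGE_FILES = {
    "simulate": "cohort/landmarks.csv",
    "extract-features": "features.csv",
    "kappa": "agreement.csv",
    "consensus": "partition_summary.json",
    "build-datasets": "datasets/CompleteAgreement.csv",
    "train": "accuracy_table.csv",
    "generalize": "generalization.csv",
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage, writing versioned plain-text outputs and a log."""
    outdir = Path(config.outdir)
    (outdir / "cohort").mkdir(parents=True, exist_ok=True)
    (outdir / "datasets").mkdir(exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "configure"
    try:
        config.to_yaml(outdir / "config.yaml")
        rng = np.random.default_rng(config.seed)

        stage = "calibrate"
        log.info("stage: calibrate")
        profiles, calibration = coh.calibrate_profiles(
            INTER_KAPPA_RANGE, INTRA_KAPPA_RANGE,
            n_sim=config.calibration_n_sim, rng=rng)

        stage = "simulate"
        log.info("stage: simulate")
        morph = (coh.morphology_from_yaml(config.morphology_yaml)
                 if config.morphology_yaml else None)
        spec = coh.CohortSpec(jitter_sd=config.jitter_sd,
                              seed=int(rng.integers(2**31)),
                              n_repeat=config.n_repeat,
                              ).scaled(config.size_factor)
        cohort = coh.generate_cohort(spec, morph_table=morph,
                                     profiles=profiles)
        subjects = [cohort.subjects[s] for s in cohort.subject_ids]
        lsets = [cohort.landmark_sets[s] for s in cohort.subject_ids]
        cio.write_landmark_csv(lsets, outdir / "cohort/landmarks.csv")
        cio.write_demographics_csv(subjects, outdir / "cohort/demographics.csv")
        panels = [cohort.panels[s] for s in sorted(cohort.panels)]
        cio.write_ratings_csv(panels, outdir / "cohort/ratings.csv")
        pd.Series(cohort.true_stage, name="true_stage").rename_axis(
            "subject_id").to_csv(outdir / "cohort/truth.csv")

        stage = "extract-features"
        log.info("stage: extract-features")
        features = extract_feature_table(lsets, subjects)
        features.to_csv(outdir / "features.csv")

        stage = "kappa"
        log.info("stage: kappa")
        agreement = agr.agreement_report(
            panels, n_boot=config.kappa_n_boot, rng=rng)
        agreement.to_frame().to_csv(outdir / "agreement.csv", index=False)

        stage = "consensus"
        log.info("stage: consensus")
        partition = agr.consensus_partition(panels)
        pd.DataFrame({
            "subject_id": sorted(partition.category),
            "category": [partition.category[s]
                         for s in sorted(partition.category)],
            "consensus": [partition.consensus.get(s, "")
                          for s in sorted(partition.category)],
        }).to_csv(outdir / "partition.csv", index=False)
        with open(outdir / "partition_summary.json", "w") as fh:
            json.dump(partition.summary(), fh, indent=2)

        stage = "build-datasets"
        log.info("stage: build-datasets")
        datasets = agr.build_datasets(features, panels, partition)
        for prov, ds in datasets.items():
            cio.write_dataset_csv(ds, outdir / f"datasets/{prov}.csv",
                                  overwrite=True)
        agr.stage_count_table(datasets).to_csv(outdir / "stage_counts.csv")

        stage = "train"
        model_seed = int(rng.integers(2**31))
        tops: dict[str, mod.ModelReport] = {}
        acc_rows = {}
        for prov in PROVENANCES:
            log.info("stage: train %s", prov)
            top, reports, selection = mod.train_dataset(
                datasets[prov], families=config.families,
                search_budget=config.search_budget, cv_folds=config.cv_folds,
                seed=model_seed, n_trees=config.selection_trees)
            tops[prov] = top
            acc_rows[prov] = {r.family: r.test_accuracy for r in reports}
            with open(outdir / f"models/{prov}.json", "w") as fh:
                json.dump({
                    "provenance": prov,
                    "selected_features": selection.selected,
                    "importances": selection.importances.round(6).to_dict(),
                    "reports": [{
                        "family": r.family,
                        "params": {k: repr(v) for k, v in r.params.items()},
                        "cv_accuracy": r.cv_accuracy,
                        "test_accuracy": r.test_accuracy,
                    } for r in reports],
                    "top_family": top.family,
                }, fh, indent=2)
            joblib.dump(top.model, outdir / f"models/{prov}_top.joblib")
        pd.DataFrame(acc_rows).loc[list(config.families),
                                   list(PROVENANCES)].to_csv(
            outdir / "accuracy_table.csv")

        stage = "generalize"
        log.info("stage: generalize")
        holdouts = gen.make_holdouts(datasets, frac=config.holdout_frac,
                                     seed=int(rng.integers(2**31)))
        report_ = gen.cross_evaluate(
            {p: tops[p].model for p in PROVENANCES}, holdouts)
        report_.to_frame().to_csv(outdir / "generalization.csv")
        with open(outdir / "ranking.json", "w") as fh:
            json.dump({"ranking_by_cv": report_.ranking()}, fh, indent=2)

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "calibration": calibration,
            "cohort_n": len(cohort),
            "config_sha256": hashlib.sha256(
                (outdir / "config.yaml").read_bytes()).hexdigest(),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        (outdir / "report.txt").write_text(report(outdir))
    except Exception:
        log.exception("stage failed: %s", stage)
        raise RuntimeError(f"pipeline failed at stage: {stage}")
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a run directory; lists missing stages."""
    run_dir = Path(run_dir)
    missing = [s for s, f in STAGE_FILES.items()
               if not (run_dir / f).exists()]
    lines = [f"run directory: {run_dir}"]
    if missing:
        lines += [f"stage missing: {s}" for s in missing]
        return "\n".join(lines) + "\n"
    summary = json.loads((run_dir / "partition_summary.json").read_text())
    lines.append(
        f"cohort: n={summary['n']}  Complete={summary['complete']} "
        f"({summary['complete_pct']:.2f}%)  Partial={summary['partial']} "
        f"({summary['partial_pct']:.2f}%)  MajorityVoting="
        f"{summary['majority_voting']} ({summary['majority_voting_pct']:.2f}%)"
        f"  Disagreement={summary['disagreement']} "
        f"({summary['disagreement_pct']:.2f}%)")
    agreement = pd.read_csv(run_dir / "agreement.csv")
    for row in agreement.itertuples():
        lines.append(
            f"kappa [{row.kind}] {row.raters}: {row.weighted_kappa:.2f} "
            f"(95% CI {row.ci_low:.2f}-{row.ci_high:.2f}, SD {row.sd:.2f})")
    acc = pd.read_csv(run_dir / "accuracy_table.csv", index_col=0)
    for prov in acc.columns:
        fam = acc[prov].idxmax()
        lines.append(f"top model [{prov}]: {fam} "
                     f"accuracy {100 * acc[prov].max():.1f}%")
    ranking = json.loads((run_dir / "ranking.json").read_text())
    lines.append("generalization ranking by ascending CV: "
                 + " > ".join(ranking["ranking_by_cv"]))
    return "\n".join(lines) + "\n"
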