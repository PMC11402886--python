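import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from cvmstage import agreement as agr
from cvmstage.datamodel import RatingPanel


class TestWeightedKappa:
    def test_identical_sequences(self):
        assert agr.weighted_kappa([1, 3, 5, 2], [1, 3, 5, 2]) == 1.0

    def test_independence_gives_zero(self):
        # observed equals expected under uniform marginals
        for scheme in ("linear", "quadratic"):
            k = agr.weighted_kappa([1, 1, 2, 2], [1, 2, 1, 2],
                                   scheme=scheme, k=2)
            assert k == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_contingency_case(self):
        # sum(wO) = 0.125, sum(wE) = 0.4375 -> kappa = 1 - 2/7
        k = agr.weighted_kappa([1, 1, 2, 3], [1, 2, 2, 3],
                               scheme="linear", k=3)
        assert k == pytest.approx(0.714286, abs=1e-6)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = rng.integers(1, 7, 30)
            b = rng.integers(1, 7, 30)
            for scheme in ("linear", "quadratic"):
                assert agr.weighted_kappa(a, b, scheme) == pytest.approx(
                    agr.weighted_kappa(b, a, scheme))

    def test_matches_reference_implementation(self, rng):
        # independent oracle: scikit-learn's weighted Cohen kappa
        for _ in range(50):
            a = rng.integers(1, 7, 40)
            b = np.where(rng.random(40) < 0.6, a, rng.integers(1, 7, 40))
            for scheme in ("linear", "quadratic"):
                ref = cohen_kappa_score(a, b, labels=list(range(1, 7)),
                                        weights=scheme)
                assert agr.weighted_kappa(a, b, scheme) == pytest.approx(ref)

    def test_linear_two_categories_equals_unweighted(self, rng):
        for _ in range(50):
            a = rng.integers(1, 3, 25)
            b = rng.integers(1, 3, 25)
            ref = cohen_kappa_score(a, b, labels=[1, 2])
            if np.isnan(ref):
                continue
            assert agr.weighted_kappa(a, b, "linear", k=2) == pytest.approx(ref)

    def test_constant_equal_raters_warn_kappa_one(self):
        with pytest.warns(UserWarning, match="zero expected"):
            assert agr.weighted_kappa([2, 2, 2], [2, 2, 2]) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            agr.weighted_kappa([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="outside"):
            agr.weighted_kappa([0, 1], [1, 1])


class TestKappaCI:
    def test_identical_sequences_degenerate_ci(self):
        a = [1, 2, 3, 4, 5, 6] * 5
        k, lo, hi, sd = agr.kappa_ci(a, a, n_boot=200, rng=0)
        assert (k, lo, hi) == (1.0, 1.0, 1.0)
        assert sd == 0.0

    def test_reproducible_with_seed(self, rng):
        a = rng.integers(1, 7, 100)
        b = np.where(rng.random(100) < 0.7, a, rng.integers(1, 7, 100))
        r1 = agr.kappa_ci(a, b, n_boot=300, rng=42)
        r2 = agr.kappa_ci(a, b, n_boot=300, rng=42)
        assert r1 == r2

    def test_ci_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (200, 2000):
            a = rng.integers(1, 7, n)
            b = np.where(rng.random(n) < 0.7, a, rng.integers(1, 7, n))
            _, lo, hi, _ = agr.kappa_ci(a, b, n_boot=400, rng=5)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_n_boot_floor(self):
        with pytest.raises(ValueError, match="n_boot"):
            agr.kappa_ci([1, 2], [1, 2], n_boot=10)


def panel(sid, stages):
    return RatingPanel(sid, {f"R{i + 1}": s for i, s in enumerate(stages)})


class TestConsensusPartition:
    @pytest.mark.parametrize("stages,category,label", [
        ((3, 3, 3), "Complete", 3),
        ((2, 3, 3), "Partial", 3),
        ((1, 2, 4), "Disagreement", None),
    ])
    def test_rule_examples(self, stages, category, label):
        part = agr.consensus_partition([panel("A", stages)])
        assert part.category["A"] == category
        assert part.consensus.get("A") == label

    def test_exhaustive_all_triples(self):
        # the partition is exhaustive/exclusive over all 216 rating triples
        panels = [panel(f"S{i}", t) for i, t in
                  enumerate(itertools.product(range(1, 7), repeat=3))]
        part = agr.consensus_partition(panels)
        counts = part.counts()
        assert sum(counts.values()) == 216
        assert counts["Complete"] == 6
        assert counts["Disagreement"] == 6 * 5 * 4
        assert counts["Partial"] == 216 - 6 - 120

    def test_requires_three_raters(self):
        with pytest.raises(ValueError, match="3"):
            agr.consensus_partition([RatingPanel("A", {"R1": 1, "R2": 2})])


class TestBuildDatasets:
    def _features(self, ids):
        return pd.DataFrame(
            {"f": np.arange(len(ids), dtype=float)},
            index=pd.Index(ids, name="subject_id"))

    def test_toy_partition_sizes(self):
        panels = [panel("A", (1, 1, 1)), panel("B", (1, 1, 2)),
                  panel("C", (1, 2, 3))]
        ds = agr.build_datasets(self._features(["A", "B", "C"]), panels)
        assert len(ds["CompleteAgreement"]) == 1
        assert len(ds["MajorityVoting"]) == 2
        assert all(len(ds[f"Rater{i}"]) == 3 for i in (1, 2, 3))
        # invariants: CA subset of MV
        assert set(ds["CompleteAgreement"].X.index) <= set(
            ds["MajorityVoting"].X.index)

    def test_perfect_agreement_makes_all_datasets_identical(self):
        panels = [panel(f"S{i}", (s, s, s))
                  for i, s in enumerate([1, 2, 3, 4, 5, 6] * 3)]
        ids = [p.subject_id for p in panels]
        ds = agr.build_datasets(self._features(ids), panels)
        base = ds["Rater1"]
        for other in ds.values():
            pd.testing.assert_series_equal(
                other.y.sort_index(), base.y.sort_index(),
                check_names=False)

    def test_unrated_features_warn_missing_features_raise(self):
        panels = [panel("A", (1, 1, 1)), panel("B", (2, 2, 2)),
                  panel("C", (3, 3, 3))]
        with pytest.warns(UserWarning, match="no"):
            agr.build_datasets(self._features(["A", "B", "C", "D"]), panels)
        with pytest.raises(ValueError, match="lack features"):
            agr.build_datasets(self._features(["A", "B"]), panels)

    def test_stage_count_table_totals(self):
        panels = [panel(f"S{i}", (s, s, s))
                  for i, s in enumerate([1, 1, 2, 3, 4, 5, 6, 6])]
        ds = agr.build_datasets(self._features([p.subject_id for p in panels]),
                                panels)
        tab = agr.stage_count_table(ds)
        assert tab.loc["Total", "Rater1"] == 8
        assert tab.loc["CS-1", "CompleteAgreement"] == 2


class TestAgreementReport:
    def test_report_covers_all_pairs_and_repeats(self):
        rng = np.random.default_rng(0)
        panels = []
        for i in range(80):
            s = int(rng.integers(1, 7))
            panels.append(RatingPanel(
                f"S{i}", {"R1": s, "R2": s, "R3": min(6, s + (i % 2))},
                {"R1": s} if i < 40 else {}))
        rep = agr.agreement_report(panels, n_boot=150, rng=1)
        assert set(rep.inter) == {("R1", "R2"), ("R1", "R3"), ("R2", "R3")}
        assert set(rep.intra) == {"R1"}
        frame = rep.to_frame()
        assert len(frame) == 4
        assert ((frame["weighted_kappa"] >= -1)
                & (frame["weighted_kappa"] <= 1)).all()
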