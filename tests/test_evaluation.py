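"""Balancing, grouped splits, voting, metric arithmetic, and the full loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecogfm.errors import ConfigurationError, ValidationError
from ecogfm.evaluation import (
    ABSTAIN,
    ChannelPrediction,
    ExperimentConfig,
    balance_classes,
    compute_metrics,
    extract_instances,
    grouped_shuffle_split,
    majority_vote,
    run_experiment,
)
from ecogfm.signal_io import NRC, PRC


def labeled(n_prc, n_nrc):
    d = {f"p{i}": PRC for i in range(n_prc)}
    d.update({f"n{i}": NRC for i in range(n_nrc)})
    return d


class TestBalance:
    def test_three_to_one_cohort(self):
        out = balance_classes(labeled(30, 90), seed=0)
        labels = list(out.values())
        assert labels.count(PRC) == 30 and labels.count(NRC) == 30
        assert all(c in out for c in labeled(30, 0))  # every PRC retained

    def test_already_balanced_unchanged(self):
        ch = labeled(5, 5)
        assert balance_classes(ch, seed=1) == ch

    def test_seed_determinism(self):
        a = balance_classes(labeled(10, 40), seed=3)
        b = balance_classes(labeled(10, 40), seed=3)
        c = balance_classes(labeled(10, 40), seed=4)
        assert a == b
        assert a != c

    def test_no_prc_rejected(self):
        with pytest.raises(ValidationError):
            balance_classes(labeled(0, 10), seed=0)

    def test_nrc_deficit_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="keeping all"):
            out = balance_classes(labeled(8, 3), seed=0)
        assert list(out.values()).count(NRC) == 3


class TestGroupedSplit:
    def test_no_channel_leakage_60_channels_30_repeats(self):
        plan = grouped_shuffle_split(labeled(30, 30), n_repeats=30, seed=5)
        assert plan.n_repeats == 30
        for train, test in plan.folds:
            assert train & test == frozenset()
            assert train | test == frozenset(labeled(30, 30))

    def test_exhaustive_on_six_channels(self):
        plan = grouped_shuffle_split(labeled(3, 3), n_repeats=50, test_fraction=0.34, seed=1)
        for train, test in plan.folds:
            for c in labeled(3, 3):
                assert (c in train) != (c in test)

    def test_stratification_floor(self):
        plan = grouped_shuffle_split(labeled(2, 20), n_repeats=10, test_fraction=0.1, seed=2)
        for _, test in plan.folds:
            assert sum(1 for c in test if c.startswith("p")) >= 1
            assert sum(1 for c in test if c.startswith("n")) >= 1

    def test_fraction_leaving_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            grouped_shuffle_split(labeled(2, 10), test_fraction=0.9, seed=0)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValidationError):
            grouped_shuffle_split(labeled(1, 5), seed=0)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "pos,total,expected",
        [
            (200, 354, PRC),  # strict majority of sub-blocks
            (0, 355, NRC),
            (177, 354, ABSTAIN),  # exact tie -> no label
            (178, 355, PRC),
            (177, 355, NRC),
        ],
    )
    def test_vote_rule(self, pos, total, expected):
        labels = [PRC] * pos + [NRC] * (total - pos)
        assert majority_vote(labels) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            majority_vote([])

    @given(st.lists(st.sampled_from([PRC, NRC]), min_size=1, max_size=400))
    def test_vote_consistent_with_stored_labels(self, labels):
        p = ChannelPrediction(channel_id="c", subblock_labels=labels)
        assert p.voted_label == majority_vote(p.subblock_labels)
        frac = labels.count(PRC) / len(labels)
        assert p.positive_fraction == frac
        assert (p.voted_label == PRC) == (frac > 0.5)


def preds_from_counts(tp, fn, tn, fp, subblocks=10):
    preds, truth = [], {}
    i = 0
    for n, t, voted in [(tp, PRC, PRC), (fn, PRC, NRC), (tn, NRC, NRC), (fp, NRC, PRC)]:
        for _ in range(n):
            cid = f"c{i}"
            i += 1
            truth[cid] = t
            dissent = [] if subblocks == 1 else [PRC if voted == NRC else NRC]
            labels = [voted] * (subblocks - len(dissent)) + dissent
            preds.append(ChannelPrediction(channel_id=cid, subblock_labels=labels))
    return preds, truth


class TestMetrics:
    def test_hand_computed_ratios(self):
        preds, truth = preds_from_counts(tp=11, fn=1, tn=9, fp=3)
        m = compute_metrics(preds, truth)
        assert m["sensitivity"] == pytest.approx(100 * 11 / 12, abs=5e-3)
        assert m["specificity"] == pytest.approx(75.0)
        assert m["accuracy"] == pytest.approx(100 * 20 / 24, abs=5e-3)

    def test_perfect_predictions(self):
        preds, truth = preds_from_counts(tp=5, fn=0, tn=5, fp=0, subblocks=1)
        m = compute_metrics(preds, truth)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (100.0, 100.0, 100.0)
        assert m["block_accuracy"] == 100.0

    def test_all_positive_predictor_on_balanced_truth(self):
        preds, truth = preds_from_counts(tp=6, fn=0, tn=0, fp=6, subblocks=1)
        m = compute_metrics(preds, truth)
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == 50.0

    def test_accuracy_identity(self):
        preds, truth = preds_from_counts(tp=7, fn=3, tn=8, fp=2)
        m = compute_metrics(preds, truth)
        P = m["tp"] + m["fn"]
        N = m["tn"] + m["fp"]
        assert m["accuracy"] == pytest.approx(
            (m["sensitivity"] * P + m["specificity"] * N) / (P + N)
        )

    def test_abstain_excluded_and_counted(self):
        preds, truth = preds_from_counts(tp=3, fn=0, tn=3, fp=0, subblocks=4)
        truth["tie"] = PRC
        preds.append(ChannelPrediction("tie", [PRC, NRC]))
        m = compute_metrics(preds, truth)
        assert m["n_abstained"] == 1
        assert m["tp"] + m["fn"] == 3  # the abstainer is in no denominator

    def test_unmatched_channel_rejected(self):
        preds, truth = preds_from_counts(tp=1, fn=0, tn=1, fp=0)
        preds.append(ChannelPrediction("ghost", [PRC]))
        with pytest.raises(ValidationError, match="ghost"):
            compute_metrics(preds, truth)


class TestConfig:
    def test_paradigm_feature_consistency(self):
        with pytest.raises(ConfigurationError):
            ExperimentConfig(paradigm="I", features=("mean", "skew"))
        with pytest.raises(ConfigurationError):
            ExperimentConfig(paradigm="II", variant="AT_AR3",
                             features=("mean", "skew"))
        with pytest.raises(ConfigurationError):
            ExperimentConfig(paradigm="III", variant="AT_AR3")
        ExperimentConfig(paradigm="II", variant="AT_AR3_LF2",
                         features=("mobility", "mean", "skew", "p2p"))
        ExperimentConfig(paradigm="III", variant="PER_STORY")


class TestFullLoop:
    def test_strong_effect_recovery_and_schema(self, tiny_cohort, tiny_experiment_kwargs):
        recs, _, _ = tiny_cohort
        cfg = ExperimentConfig(
            paradigm="I", variant="AT_AR3", features=("mobility",),
            n_repeats=3, seed=21, **tiny_experiment_kwargs,
        )
        res = run_experiment(recs, cfg)
        assert set(res.report.per_repeat.columns) >= {
            "repeat", "block_accuracy", "sensitivity", "specificity", "accuracy",
        }
        for train, test in res.folds:
            assert train & test == frozenset()
        assert res.report.mean["accuracy"] >= 75.0

    def test_report_schema_identical_across_paradigms(self, tiny_cohort, tiny_experiment_kwargs):
        recs, _, _ = tiny_cohort
        base = dict(n_repeats=1, seed=5, **tiny_experiment_kwargs)
        r1 = run_experiment(recs, ExperimentConfig(
            paradigm="I", variant="AT1", features=("activity",), **base))
        r2 = run_experiment(recs, ExperimentConfig(
            paradigm="II", variant="AT_AR3_LF2", features=("mobility", "mean"), **base))
        r3 = run_experiment(recs, ExperimentConfig(
            paradigm="III", variant="PER_STORY", features=("mobility",), **base))
        cols = list(r1.report.per_repeat.columns)
        assert list(r2.report.per_repeat.columns) == cols
        assert list(r3.report.per_repeat.columns) == cols

    def test_control_condition_twin_runs(self, tiny_cohort, tiny_experiment_kwargs):
        recs, _, _ = tiny_cohort
        cfg = ExperimentConfig(
            paradigm="I", variant="AT_AR3", features=("activity",),
            condition="control", n_repeats=1, seed=9, **tiny_experiment_kwargs,
        )
        res = run_experiment(recs, cfg)
        # control blocks carry no class signal in the generator
        assert np.isfinite(res.report.mean["accuracy"])

    def test_data_driven_ar_order(self, tiny_cohort, tiny_experiment_kwargs):
        recs, _, _ = tiny_cohort
        kw = dict(tiny_experiment_kwargs)
        cfg = ExperimentConfig(paradigm="I", variant="AT_AR3", features=("mobility",),
                               ar_order_criterion="aic", **kw)
        inst = extract_instances(recs, cfg)
        # AIC over 1..ar_order on a colored-noise block picks a usable order
        assert 1 <= inst.x_freq.shape[-1] <= kw["ar_order"]
        res = run_experiment(recs[:6] + recs[-6:], ExperimentConfig(
            paradigm="I", variant="AT_AR3", features=("mobility",),
            ar_order_criterion="aic", n_repeats=1, seed=2, **kw))
        assert np.isfinite(res.report.mean["accuracy"])

    def test_instance_extraction_shapes(self, tiny_cohort, tiny_experiment_kwargs):
        recs, _, _ = tiny_cohort
        kw = dict(tiny_experiment_kwargs)
        cfg = ExperimentConfig(paradigm="I", variant="AT_AR3",
                               features=("mobility",), **kw)
        inst = extract_instances(recs, cfg)
        # 400-sample blocks, 40/20 windows -> 19 windows; subblocks 8/3 -> 4/block
        assert inst.x_time.shape[1:] == (8, 1)
        n_sub_per_channel = 4 * 5  # 4 sub-blocks x 5 active blocks
        assert inst.x_time.shape[0] == len(recs) * n_sub_per_channel
        assert inst.x_freq.shape == (inst.x_time.shape[0], 8)
        cfg3 = ExperimentConfig(paradigm="III", variant="PER_STORY",
                                features=("mobility",), **kw)
        inst3 = extract_instances(recs, cfg3)
        assert inst3.x_time.shape[1:] == (5, 8, 1)
        assert inst3.x_freq.shape[1:] == (5, 8)
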