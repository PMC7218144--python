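"""Step 5 and validation: balancing, grouped cross-validation, voting, metrics.

The unit of classification is the sub-block — a short overlapping segment of
a block's window-feature sequence — but the quantity of clinical interest is
the channel label, obtained by majority voting over all of a channel's
sub-block predictions: positive response if strictly more than half the
sub-blocks are called positive, negative if strictly fewer, and no label
(abstain) on an exact tie.

Validation is repeated shuffle-split, grouped by channel: every sub-block of
a channel travels with it, so no channel contributes to both the training
and test side of any repeat. Because negative channels outnumber positive
ones about 3:1 on clinical grids, each repeat first rebalances by
undersampling the negatives (with a repeat-specific seed, so the subsampling
variability is averaged over) and then draws a class-stratified test set.

Reported metrics, all in percent: sensitivity TP/(TP+FN) over true-positive
channels, specificity TN/(TN+FP) over true-negative channels, channel
accuracy (TP+TN)/all, and block accuracy — the sub-block-level correct
fraction under the channel's label. Abstaining channels are counted and
excluded from the ratio denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .freq_features import ar_feature_vector, select_ar_order
from .networks import (
    ModelSpec,
    SubblockDataset,
    TrainedModel,
    build_model,
    predict_subblocks,
    small_spec,
    train_model,
)
from .nn.train import TrainConfig
from .segmentation import extract_blocks, sliding_windows, trim_to_task
from .signal_io import NRC, PRC, AnnotatedRecording
from .time_features import FEATURE_NAMES, feature_matrix

ABSTAIN = "abstain"


# ---------------------------------------------------------------------------
# class balancing and grouped splits


def balance_classes(
    channels: dict[str, str], seed: int
) -> dict[str, str]:
    """Undersample negative channels to match the positives, preserving all PRCs.

    ``channels`` maps channel id -> truth label. The NRC subset is drawn
    uniformly without replacement with the given seed; a deficit of NRCs
    keeps them all with a warning.
    """
    prc = sorted(c for c, l in channels.items() if l == PRC)
    nrc = sorted(c for c, l in channels.items() if l == NRC)
    if not prc:
        raise ValidationError("cannot balance: no positive-response channels")
    if len(nrc) < len(prc):
        warnings.warn(
            f"only {len(nrc)} NRCs for {len(prc)} PRCs; keeping all NRCs",
            stacklevel=2,
        )
        keep = nrc
    else:
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(nrc, size=len(prc), replace=False))
    return {c: channels[c] for c in prc + list(keep)}


@dataclass(frozen=True)
class CVFoldPlan:
    """Repeated channel-grouped train/test partitions (no channel leakage)."""

    n_repeats: int
    test_fraction: float
    seed: int
    folds: tuple[tuple[frozenset, frozenset], ...]  # (train ids, test ids)

    def __post_init__(self):
        for train, test in self.folds:
            assert not (train & test), "channel appears on both fold sides"


def grouped_shuffle_split(
    channels: dict[str, str],
    n_repeats: int = 30,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> CVFoldPlan:
    """Class-stratified random train/test channel partitions, repeated.

    Each repeat draws an independent test set with at least one channel per
    class on each side; all of a channel's data stays on its side.
    """
    prc = sorted(c for c, l in channels.items() if l == PRC)
    nrc = sorted(c for c, l in channels.items() if l == NRC)
    if len(prc) < 2 or len(nrc) < 2:
        raise ValidationError(
            f"need >= 2 channels per class to split, got {len(prc)} PRC / {len(nrc)} NRC"
        )
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n_test_p = max(1, round(test_fraction * len(prc)))
    n_test_n = max(1, round(test_fraction * len(nrc)))
    if n_test_p >= len(prc) or n_test_n >= len(nrc):
        raise ValidationError(
            f"test_fraction {test_fraction} leaves a class empty in training"
        )
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_repeats):
        tp = set(rng.choice(prc, size=n_test_p, replace=False))
        tn = set(rng.choice(nrc, size=n_test_n, replace=False))
        test = frozenset(tp | tn)
        train = frozenset(set(prc) | set(nrc)) - test
        folds.append((train, test))
    return CVFoldPlan(
        n_repeats=n_repeats,
        test_fraction=test_fraction,
        seed=seed,
        folds=tuple(folds),
    )


# ---------------------------------------------------------------------------
# voting


@dataclass
class ChannelPrediction:
    """Per-channel outcome: sub-block labels, the vote, and its margin."""

    channel_id: str
    subblock_labels: list[str]
    voted_label: str = field(init=False)
    positive_fraction: float = field(init=False)

    def __post_init__(self):
        self.voted_label = majority_vote(self.subblock_labels)
        self.positive_fraction = sum(
            1 for l in self.subblock_labels if l == PRC
        ) / len(self.subblock_labels)


def majority_vote(subblock_labels: Sequence[str]) -> str:
    """PRC if > 50% of sub-blocks are positive, NRC if < 50%, abstain on a tie."""
    if len(subblock_labels) == 0:
        raise ValidationError("cannot vote on an empty label list")
    pos = sum(1 for l in subblock_labels if l == PRC)
    neg = len(subblock_labels) - pos
    if pos > neg:
        return PRC
    if pos < neg:
        return NRC
    return ABSTAIN


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricReport:
    """Per-repeat metric table (percent) with mean +/- sd aggregation."""

    per_repeat: pd.DataFrame  # columns: repeat, block_accuracy, sensitivity, ...
    n_abstained: int = 0

    METRICS = ("block_accuracy", "sensitivity", "specificity", "accuracy")

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat[list(self.METRICS)].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_repeat[list(self.METRICS)].std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.std})

    def __str__(self) -> str:
        lines = [
            f"  {m:>15s}: {self.mean[m]:6.2f} +/- {0.0 if np.isnan(self.std[m]) else self.std[m]:5.2f} %"
            for m in self.METRICS
        ]
        if self.n_abstained:
            lines.append(f"  abstained channels: {self.n_abstained}")
        return "\n".join(lines)


def compute_metrics(
    predictions: Sequence[ChannelPrediction],
    truth: dict[str, str],
    repeat: int = 0,
) -> dict:
    """One repeat's metric row from voted channel predictions and truth labels.

    Abstaining channels are excluded from every denominator and counted in
    ``n_abstained``; block accuracy scores each sub-block label against its
    channel's truth.
    """
    missing = [p.channel_id for p in predictions if p.channel_id not in truth]
    if missing:
        raise ValidationError(f"no truth label for channel(s) {missing}")
    tp = fn = tn = fp = 0
    abstained = 0
    blocks_right = blocks_total = 0
    for p in predictions:
        t = truth[p.channel_id]
        blocks_right += sum(1 for l in p.subblock_labels if l == t)
        blocks_total += len(p.subblock_labels)
        if p.voted_label == ABSTAIN:
            abstained += 1
            continue
        if t == PRC:
            tp += p.voted_label == PRC
            fn += p.voted_label == NRC
        else:
            tn += p.voted_label == NRC
            fp += p.voted_label == PRC
    def pct(num, den):
        return 100.0 * num / den if den else np.nan
    return {
        "repeat": repeat,
        "block_accuracy": pct(blocks_right, blocks_total),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "accuracy": pct(tp + tn, tp + tn + fp + fn),
        "n_abstained": abstained,
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


# ---------------------------------------------------------------------------
# the full experiment loop


PARADIGMS = ("I", "II", "III")
_FUSION_VARIANTS = {"AT_AR3_EF", "AT_AR3_LF1", "AT_AR3_LF2"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one training-and-evaluation run depends on.

    Paradigm I trains one variant on a single hand-crafted feature over all
    active data; paradigm II fuses several features (early or late) with the
    AT-AR3 backbone; paradigm III trains per-story modules and merges them.
    ``condition="control"`` turns any variant into its control-data twin
    (the CT rows of the result tables).
    """

    paradigm: str = "I"
    variant: str = "AT_AR3"
    features: tuple[str, ...] = ("mobility",)
    condition: str = "active"
    window_width: int = 600
    window_stride: int = 100
    subblock_windows: int = 20  # sub-block length, in windows
    subblock_stride: int = 5  # overlap between consecutive sub-blocks
    ar_order: int = 20
    ar_include_rho: bool = False
    ar_order_criterion: str = "fixed"  # fixed | aic | fpe
    n_repeats: int = 30
    test_fraction: float = 0.2
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.3
    patience: int = 10
    small_model: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ConfigurationError(f"unknown paradigm {self.paradigm!r}")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown feature(s) {sorted(unknown)}")
        if self.paradigm == "I" and len(self.features) != 1:
            raise ConfigurationError("paradigm I uses exactly one feature")
        if self.paradigm == "II":
            if self.variant not in _FUSION_VARIANTS:
                raise ConfigurationError(
                    f"paradigm II needs a feature-fusion variant, got {self.variant}"
                )
            if len(self.features) < 2:
                raise ConfigurationError("paradigm II needs >= 2 features")
        if self.paradigm == "III" and self.variant != "PER_STORY":
            raise ConfigurationError("paradigm III uses the PER_STORY variant")
        if self.condition not in ("active", "control"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.ar_order_criterion not in ("fixed", "aic", "fpe"):
            raise ConfigurationError(
                f"unknown ar_order_criterion {self.ar_order_criterion!r}"
            )

    @property
    def uses_frequency_path(self) -> bool:
        return self.variant not in ("AT1", "AT2")

    @property
    def ar_dim(self) -> Optional[int]:
        if not self.uses_frequency_path:
            return None
        return self.ar_order + (1 if self.ar_include_rho else 0)

    def model_spec(self, n_stories: int = 5, ar_dim: Optional[int] = None) -> ModelSpec:
        kwargs = dict(
            variant=self.variant,
            n_windows=self.subblock_windows,
            n_features=len(self.features),
            ar_dim=self.ar_dim if ar_dim is None else ar_dim,
            n_stories=n_stories,
        )
        if self.small_model:
            return small_spec(**kwargs)
        return ModelSpec(**kwargs, dropout=self.dropout)

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            dropout=self.dropout,
            patience=self.patience,
            seed=seed,
        )


def _derive_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((seed,) + key).generate_state(1)[0] % (2**31))


@dataclass
class InstanceTable:
    """All sub-block instances of a cohort, ready for fold slicing."""

    x_time: np.ndarray
    x_freq: Optional[np.ndarray]
    channel_ids: np.ndarray
    labels: np.ndarray  # truth label per instance, "PRC"/"NRC"

    def for_channels(self, ids) -> np.ndarray:
        return np.isin(self.channel_ids, list(ids))


def extract_instances(
    recordings: Sequence[AnnotatedRecording], config: ExperimentConfig
) -> InstanceTable:
    """Feature extraction for a whole cohort, deterministic per channel.

    Each selected-condition block yields a window-feature sequence, cut into
    overlapping sub-blocks of ``subblock_windows`` rows; every sub-block
    pairs with its parent block's AR coefficient vector. For paradigm III
    the sub-blocks at the same within-block position are aligned across the
    five stories into one multi-story instance.
    """
    per_story = config.paradigm == "III"
    ar_order = config.ar_order
    if config.uses_frequency_path and config.ar_order_criterion != "fixed":
        # one order for the whole experiment (feature vectors must share a
        # length): selected on the first channel's first selected block
        first = extract_blocks(trim_to_task(recordings[0]))
        blocks0 = first.active() if config.condition == "active" else first.control()
        ar_order = select_ar_order(
            blocks0[0][1],
            range(1, config.ar_order + 1),
            criterion=config.ar_order_criterion,
            fixed_order=config.ar_order,
        )
    xs, fs_, cids, labs = [], [], [], []
    for rec in recordings:
        if rec.truth_label is None:
            raise ValidationError(f"channel {rec.channel_id} has no truth label")
        bs = extract_blocks(trim_to_task(rec))
        blocks = bs.active() if config.condition == "active" else bs.control()
        seqs, ars = [], []
        for ann, x in blocks:
            ws = sliding_windows(x, config.window_width, config.window_stride)
            feats = feature_matrix(ws.windows, config.features)
            if not np.isfinite(feats).all():
                raise ValidationError(
                    f"channel {rec.channel_id}: non-finite features in block "
                    f"[{ann.start_sample}, {ann.end_sample})"
                )
            seqs.append(feats)
            if config.uses_frequency_path:
                ars.append(
                    ar_feature_vector(
                        x, ar_order, include_rho=config.ar_include_rho
                    ).values
                )
        n_win = min(len(s) for s in seqs)
        sub_w, sub_s = config.subblock_windows, config.subblock_stride
        if sub_w > n_win:
            raise ConfigurationError(
                f"subblock_windows {sub_w} exceeds per-block window count {n_win}"
            )
        starts = range(0, n_win - sub_w + 1, sub_s)
        if per_story:
            for s0 in starts:
                xs.append(np.stack([s[s0 : s0 + sub_w] for s in seqs]))
                if config.uses_frequency_path:
                    fs_.append(np.stack(ars))
                cids.append(rec.channel_id)
                labs.append(rec.truth_label)
        else:
            for seq, ar in zip(seqs, ars if ars else [None] * len(seqs)):
                for s0 in starts:
                    xs.append(seq[s0 : s0 + sub_w])
                    if ar is not None:
                        fs_.append(ar)
                    cids.append(rec.channel_id)
                    labs.append(rec.truth_label)
    return InstanceTable(
        x_time=np.stack(xs),
        x_freq=np.stack(fs_) if fs_ else None,
        channel_ids=np.array(cids),
        labels=np.array(labs),
    )


@dataclass
class ExperimentResult:
    """Metric report plus per-repeat fold plans and channel-level votes."""

    config: ExperimentConfig
    report: MetricReport
    folds: list[tuple[frozenset, frozenset]]
    predictions: list[list[ChannelPrediction]]  # per repeat
    models: list[TrainedModel] = field(default_factory=list)


def run_experiment(
    recordings: Sequence[AnnotatedRecording],
    config: ExperimentConfig,
    keep_models: bool = False,
    instances: Optional[InstanceTable] = None,
) -> ExperimentResult:
    """The full loop: balance, split, train, predict, vote, score — repeated.

    Feature extraction runs once per cohort (pass ``instances`` to reuse it
    across experiments on the same cohort); balancing and the stratified
    channel split are redone with a derived seed in every repeat.
    """
    truth = {r.channel_id: r.truth_label for r in recordings}
    if instances is None:
        instances = extract_instances(recordings, config)
    n_stories = (
        instances.x_time.shape[1] if config.paradigm == "III" else 5
    )
    rows, all_folds, all_preds, models = [], [], [], []
    for r in range(config.n_repeats):
        seed_r = _derive_seed(config.seed, r)
        balanced = balance_classes(truth, seed_r)
        plan = grouped_shuffle_split(
            balanced, n_repeats=1, test_fraction=config.test_fraction, seed=seed_r
        )
        train_ids, test_ids = plan.folds[0]
        all_folds.append((train_ids, test_ids))

        tr_mask = instances.for_channels(train_ids)
        ds = SubblockDataset(
            x_time=instances.x_time[tr_mask],
            y=(instances.labels[tr_mask] == PRC).astype(float),
            channel_ids=instances.channel_ids[tr_mask],
            x_freq=None if instances.x_freq is None else instances.x_freq[tr_mask],
        )
        ar_dim = None if instances.x_freq is None else instances.x_freq.shape[-1]
        model = build_model(config.model_spec(n_stories, ar_dim=ar_dim), seed=seed_r)
        trained = train_model(model, ds, config.train_config(seed_r))

        preds = []
        for cid in sorted(test_ids):
            m = instances.channel_ids == cid
            probs, labels = predict_subblocks(
                trained,
                instances.x_time[m],
                None if instances.x_freq is None else instances.x_freq[m],
            )
            preds.append(ChannelPrediction(channel_id=cid, subblock_labels=list(labels)))
        rows.append(compute_metrics(preds, truth, repeat=r))
        all_preds.append(preds)
        if keep_models:
            models.append(trained)
    per_repeat = pd.DataFrame(rows)
    report = MetricReport(
        per_repeat=per_repeat, n_abstained=int(per_repeat["n_abstained"].sum())
    )
    return ExperimentResult(
        config=config,
        report=report,
        folds=all_folds,
        predictions=all_preds,
        models=models,
    )
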