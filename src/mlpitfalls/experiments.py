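"""Paired pitfall-vs-correct experiments and the batch-effect experiment.

Each leakage experiment builds two models per repetition from the *same*
generated dataset — one incorporating the pitfall (transform before the
split, or a row-level split of per-patient data), one avoiding it — and
compares the two test-set F1 vectors over many repetitions with the Wilcoxon
rank-sum test.  Because every generator default carries **zero class
signal**, the correct arm can only perform at chance; any excess in the
pitfall arm is pure leakage.

The batch-effect experiment trains a single classifier on a dataset whose
class label is perfectly confounded with the acquisition source and then
evaluates it on an external dataset that breaks the confound.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

from .errors import ConfigurationError, DegenerateDataError
from .metrics import (
    MetricReport,
    classification_report,
    confusion,
    summarize_scores,
    wilcoxon_rank_sum,
)
from .splitting import (
    OrderingPolicy,
    SplitKind,
    Transform,
    When,
    materialize,
)
from .synthetic_data import (
    BatchConfig,
    PatchConfig,
    TabularConfig,
    gen_batch_dataset,
    gen_patient_patches,
    gen_tabular,
)
from .table import LabeledTable

__all__ = [
    "ExperimentKind",
    "ClassifierKind",
    "ExperimentConfig",
    "ExperimentResult",
    "BatchEffectResult",
    "default_config",
    "train_and_score",
    "run_paired_experiment",
    "run_batch_effect",
    "summarize_experiment",
    "chance_f1_estimate",
]


class ExperimentKind(str, enum.Enum):
    OVERSAMPLING = "oversampling"
    AUGMENTATION = "augmentation"
    PATIENT_SPLIT = "patient_split"
    FEATURE_SELECTION = "feature_selection"
    BATCH_EFFECT = "batch_effect"


class ClassifierKind(str, enum.Enum):
    NEAREST_NEIGHBOR_1 = "1nn"
    RANDOM_FOREST = "random_forest"
    LOGISTIC = "logistic"


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    ``generator`` is the synthetic-data config whose defaults define the
    study conditions; ``seed`` is the master seed from which all per-
    repetition sub-seeds are derived.
    """

    kind: ExperimentKind
    generator: TabularConfig | PatchConfig | BatchConfig
    repetitions: int = 100
    classifier: ClassifierKind = ClassifierKind.NEAREST_NEIGHBOR_1
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    copies_per_sample: int = 3
    jitter_sigma: float = 0.1
    k_features: int = 10
    seed: int = 0
    max_redraws: int = 10

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")


@dataclass
class ExperimentResult:
    kind: ExperimentKind
    pitfall_arm: list[MetricReport]
    correct_arm: list[MetricReport]
    pitfall_audits: list[dict[str, int]]
    correct_audits: list[dict[str, int]]
    wilcoxon: tuple[float, float] | None
    mean_f1_delta: float
    # per-repetition correct-arm composition, for chance-level comparisons:
    # (n_test, n_test_positive, train_positive_fraction)
    correct_test_composition: list[tuple[int, int, float]] = field(default_factory=list)

    def f1_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([_f1(r) for r in self.pitfall_arm]),
            np.array([_f1(r) for r in self.correct_arm]),
        )


@dataclass
class BatchEffectResult:
    internal: MetricReport
    external_correct_fraction: float


def default_config(
    kind: ExperimentKind, seed: int = 0, repetitions: int = 100
) -> ExperimentConfig:
    """The documented null-signal, leak-prone default conditions per pitfall.

    Every generator carries zero intrinsic class signal, so correct handling
    yields chance-level performance and the pitfall arm's gain isolates the
    leakage (or batch) effect:

    * oversampling — 100 patients, 10 features, 10 % positive class;
    * augmentation — 100 balanced patients, 3 jittered copies per sample;
    * patient split — 20 patients × 30 patches with strong (SD 3) patient
      signatures;
    * feature selection — 100 balanced patients, 1000 features, top 10 kept;
    * batch effect — 500 samples per source, orthogonal source signatures of
      magnitude 3.
    """
    kind = ExperimentKind(kind)
    if kind is ExperimentKind.OVERSAMPLING:
        gen = TabularConfig(n_patients=100, n_features=10, class_fraction=0.1)
    elif kind is ExperimentKind.AUGMENTATION:
        gen = TabularConfig(n_patients=100, n_features=10, class_fraction=0.5)
    elif kind is ExperimentKind.PATIENT_SPLIT:
        gen = PatchConfig(
            n_patients=20,
            patches_per_patient=30,
            n_features=10,
            signature_strength=3.0,
            class_signal=0.0,
        )
    elif kind is ExperimentKind.FEATURE_SELECTION:
        gen = TabularConfig(n_patients=100, n_features=1000, class_fraction=0.5)
    else:
        # linear model: the analogue of a trained network picking up the
        # source signature; 1-NN would dilute the signature with feature noise
        gen = BatchConfig(n_per_source=500, n_features=10, signature_strength=3.0)
        return ExperimentConfig(
            kind=kind,
            generator=gen,
            seed=seed,
            repetitions=repetitions,
            classifier=ClassifierKind.LOGISTIC,
        )
    return ExperimentConfig(kind=kind, generator=gen, seed=seed, repetitions=repetitions)


# ---------------------------------------------------------------------------
# Classifier plumbing
# ---------------------------------------------------------------------------


def _make_classifier(kind: ClassifierKind, seed: int):
    if kind is ClassifierKind.NEAREST_NEIGHBOR_1:
        return KNeighborsClassifier(n_neighbors=1)
    if kind is ClassifierKind.RANDOM_FOREST:
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    return LogisticRegression(max_iter=1000, random_state=seed)


def train_and_score(
    train: LabeledTable,
    test: LabeledTable,
    classifier: ClassifierKind = ClassifierKind.NEAREST_NEIGHBOR_1,
    seed: int = 0,
) -> MetricReport:
    """Standardize on training statistics, fit, and score on the test set."""
    if len(np.unique(train.labels)) < 2:
        raise DegenerateDataError("training set must contain both classes")
    mean = train.features.mean(axis=0)
    sd = train.features.std(axis=0)
    sd[sd == 0] = 1.0
    model = _make_classifier(ClassifierKind(classifier), seed)
    model.fit((train.features - mean) / sd, train.labels)
    pred = model.predict((test.features - mean) / sd)
    return classification_report(confusion(test.labels, pred))


def _f1(report: MetricReport) -> float:
    return 0.0 if "f1" in report.undefined else float(report.f1)


def _sub_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Paired experiments
# ---------------------------------------------------------------------------

_ARMS: dict[ExperimentKind, tuple[tuple[OrderingPolicy, SplitKind], tuple[OrderingPolicy, SplitKind]]] = {
    ExperimentKind.OVERSAMPLING: (
        (OrderingPolicy(Transform.OVERSAMPLE, When.BEFORE_SPLIT), SplitKind.RANDOM),
        (OrderingPolicy(Transform.OVERSAMPLE, When.AFTER_SPLIT), SplitKind.RANDOM),
    ),
    ExperimentKind.AUGMENTATION: (
        (OrderingPolicy(Transform.AUGMENT, When.BEFORE_SPLIT), SplitKind.RANDOM),
        (OrderingPolicy(Transform.AUGMENT, When.AFTER_SPLIT), SplitKind.RANDOM),
    ),
    ExperimentKind.PATIENT_SPLIT: (
        (OrderingPolicy(Transform.NONE, When.AFTER_SPLIT), SplitKind.RANDOM),
        (OrderingPolicy(Transform.NONE, When.AFTER_SPLIT), SplitKind.GROUPED),
    ),
    ExperimentKind.FEATURE_SELECTION: (
        (OrderingPolicy(Transform.SELECT_FEATURES, When.BEFORE_SPLIT), SplitKind.RANDOM),
        (OrderingPolicy(Transform.SELECT_FEATURES, When.AFTER_SPLIT), SplitKind.RANDOM),
    ),
}


def arm_policies(
    kind: ExperimentKind,
) -> tuple[tuple[OrderingPolicy, SplitKind], tuple[OrderingPolicy, SplitKind]]:
    """(pitfall, correct) ordering/split choices for a paired experiment."""
    return _ARMS[ExperimentKind(kind)]


def _generate(config: ExperimentConfig, data_seed: int) -> LabeledTable:
    gen = replace(config.generator, seed=data_seed)
    if isinstance(gen, PatchConfig):
        return gen_patient_patches(gen)
    if isinstance(gen, TabularConfig):
        return gen_tabular(gen)
    raise ConfigurationError(f"generator {type(gen).__name__} has no paired experiment")


def _run_arm(
    table: LabeledTable,
    policy: OrderingPolicy,
    split_kind: SplitKind,
    config: ExperimentConfig,
    split_seed: int,
    clf_seed: int,
) -> tuple[MetricReport, dict[str, int]]:
    train, _val, test, audit = materialize(
        table,
        policy,
        split_kind=split_kind,
        ratios=config.ratios,
        seed=split_seed,
        copies_per_sample=config.copies_per_sample,
        jitter_sigma=config.jitter_sigma,
        k_features=config.k_features,
    )
    if len(np.unique(train.labels)) < 2 or test.labels.sum() == 0:
        raise DegenerateDataError("degenerate train or test subset")
    # chance predicted-positive rate: share of *distinct* training examples
    # that are positive (duplicates and jittered copies do not move a
    # memorization classifier's decision geometry)
    _, first_idx = np.unique(train.provenance_id.astype(str), return_index=True)
    composition = (
        len(test),
        int(test.labels.sum()),
        float(train.labels[first_idx].mean()),
    )
    return train_and_score(train, test, config.classifier, seed=clf_seed), audit, composition


def run_paired_experiment(
    config: ExperimentConfig,
    pitfall_policy: tuple[OrderingPolicy, SplitKind] | None = None,
    correct_policy: tuple[OrderingPolicy, SplitKind] | None = None,
) -> ExperimentResult:
    """Run the paired harness: both arms per repetition on identical data.

    Within a repetition both arms see the same generated table and the same
    classifier seed; only the transform ordering / split kind (and the split
    randomness, which is arm-specific) differ.  A repetition whose split
    leaves a single-class training set or a positive-free test set is redrawn
    with a fresh derived seed, up to ``config.max_redraws`` times.
    """
    if config.kind is ExperimentKind.BATCH_EFFECT:
        raise ConfigurationError("use run_batch_effect for BATCH_EFFECT")
    default_pitfall, default_correct = arm_policies(config.kind)
    pitfall_policy = pitfall_policy or default_pitfall
    correct_policy = correct_policy or default_correct

    pitfall_reports: list[MetricReport] = []
    correct_reports: list[MetricReport] = []
    pitfall_audits: list[dict[str, int]] = []
    correct_audits: list[dict[str, int]] = []
    compositions: list[tuple[int, int, float]] = []

    for rep in range(config.repetitions):
        for attempt in range(config.max_redraws + 1):
            data_seed = _sub_seed(config.seed, rep, attempt, 0)
            clf_seed = _sub_seed(config.seed, rep, attempt, 1)
            split_seed = _sub_seed(config.seed, rep, attempt, 2)
            table = _generate(config, data_seed)
            try:
                rep_p, audit_p, _ = _run_arm(
                    table, *pitfall_policy, config, split_seed, clf_seed,
                )
                rep_c, audit_c, comp_c = _run_arm(
                    table, *correct_policy, config, split_seed, clf_seed,
                )
            except DegenerateDataError:
                if attempt == config.max_redraws:
                    raise
                continue
            break
        pitfall_reports.append(rep_p)
        correct_reports.append(rep_c)
        pitfall_audits.append(audit_p)
        correct_audits.append(audit_c)
        compositions.append(comp_c)

    f1_p = np.array([_f1(r) for r in pitfall_reports])
    f1_c = np.array([_f1(r) for r in correct_reports])
    wilcoxon: tuple[float, float] | None
    if config.repetitions < 2:
        wilcoxon = None
    else:
        try:
            wilcoxon = wilcoxon_rank_sum(f1_p, f1_c)
        except DegenerateDataError:
            wilcoxon = None
    return ExperimentResult(
        kind=config.kind,
        pitfall_arm=pitfall_reports,
        correct_arm=correct_reports,
        pitfall_audits=pitfall_audits,
        correct_audits=correct_audits,
        wilcoxon=wilcoxon,
        mean_f1_delta=float(f1_p.mean() - f1_c.mean()),
        correct_test_composition=compositions,
    )


def run_batch_effect(config: ExperimentConfig) -> BatchEffectResult:
    """Train on the confounded internal set; test internally and externally.

    The internal set is split 60/20/20 at random; the internal report is
    computed on its test subset.  The external score is the fraction of
    external samples (all class 0, bearing the class-1 source's signature)
    the model classifies correctly.
    """
    if config.kind is not ExperimentKind.BATCH_EFFECT:
        raise ConfigurationError("config.kind must be BATCH_EFFECT")
    if not isinstance(config.generator, BatchConfig):
        raise ConfigurationError("BATCH_EFFECT requires a BatchConfig generator")
    for attempt in range(config.max_redraws + 1):
        gen = replace(config.generator, seed=_sub_seed(config.seed, 0, attempt, 0))
        internal, external = gen_batch_dataset(gen)
        try:
            train, _val, test, _audit = materialize(
                internal,
                OrderingPolicy(Transform.NONE),
                split_kind=SplitKind.RANDOM,
                ratios=config.ratios,
                seed=_sub_seed(config.seed, 0, attempt, 2),
            )
            if len(np.unique(train.labels)) < 2 or test.labels.sum() == 0:
                raise DegenerateDataError("degenerate internal split")
            mean = train.features.mean(axis=0)
            sd = train.features.std(axis=0)
            sd[sd == 0] = 1.0
            model = _make_classifier(
                ClassifierKind(config.classifier), _sub_seed(config.seed, 0, attempt, 1)
            )
            model.fit((train.features - mean) / sd, train.labels)
            internal_report = classification_report(
                confusion(test.labels, model.predict((test.features - mean) / sd))
            )
            ext_pred = model.predict((external.features - mean) / sd)
            external_fraction = float((ext_pred == external.labels).mean())
        except DegenerateDataError:
            if attempt == config.max_redraws:
                raise
            continue
        return BatchEffectResult(
            internal=internal_report, external_correct_fraction=external_fraction
        )
    raise DegenerateDataError("unreachable")  # pragma: no cover


def summarize_experiment(result: ExperimentResult) -> list[dict]:
    """Table-style rows: per-arm F1 summary plus the paired comparison."""
    f1_p, f1_c = result.f1_vectors()
    if f1_p.size == 0 or f1_c.size == 0:
        raise ValueError("cannot summarize an empty arm")
    rows = []
    for arm, f1s in (("pitfall", f1_p), ("correct", f1_c)):
        s = summarize_scores(f1s)
        rows.append(
            {
                "experiment": result.kind.value,
                "arm": arm,
                "mean_f1": s["mean"],
                "sd_f1": s["sd"],
                "min_f1": s["min"],
                "max_f1": s["max"],
                "mean_f1_delta": result.mean_f1_delta,
                "wilcoxon_z": None if result.wilcoxon is None else result.wilcoxon[0],
                "wilcoxon_p": None if result.wilcoxon is None else result.wilcoxon[1],
            }
        )
    return rows


def chance_f1_estimate(
    test_composition: list[tuple[int, int, float]],
    reps_per_setting: int = 400,
    seed: int = 0,
) -> float:
    """Monte Carlo mean F1 of a label-blind predictor — the chance level.

    For each realized test-set composition ``(n_test, n_positive, q)`` from
    an experiment's correct arm, a predictor outputs positives independently
    of the truth at rate ``q`` (the training positive fraction, which is what
    a classifier fitted to label-independent features predicts at).  The mean
    F1 over simulations is the chance level implied by class balance, against
    which an honest correct arm should sit.
    """
    rng = np.random.default_rng(seed)
    totals = []
    for n_test, n_pos, q in test_composition:
        y = np.zeros(n_test, dtype=bool)
        y[:n_pos] = True
        pred = rng.random((reps_per_setting, n_test)) < q
        tp = (pred & y).sum(axis=1)
        denom = pred.sum(axis=1) + n_pos  # 2tp + fp + fn
        scores = np.where(denom == 0, 0.0, 2 * tp / np.maximum(denom, 1))
        totals.append(scores.mean())
    return float(np.mean(totals))
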