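"""Train/validation/test splitting, leak-prone transforms, and a leakage auditor.

The module makes the *ordering* of a preprocessing transform relative to the
data split an explicit, first-class choice (:class:`OrderingPolicy`): applied
``BEFORE_SPLIT`` a transform sees the whole dataset (the pitfall), applied
``AFTER_SPLIT`` it sees training rows only (the correct procedure; for
feature selection, the indices chosen on the training rows are then applied
to validation and test).  :func:`leakage_audit` quantifies the resulting
dependence between subsets by counting provenance and patient identifiers
that span more than one subset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateDataError, InfeasibleSplitError
from .table import LabeledTable

__all__ = [
    "Subset",
    "Transform",
    "When",
    "SplitKind",
    "OrderingPolicy",
    "SplitAssignment",
    "split_random",
    "split_grouped",
    "oversample",
    "augment",
    "select_top_features",
    "materialize",
    "leakage_audit",
]


class Subset(enum.IntEnum):
    TRAIN = 0
    VAL = 1
    TEST = 2


class Transform(str, enum.Enum):
    OVERSAMPLE = "oversample"
    AUGMENT = "augment"
    SELECT_FEATURES = "select_features"
    NONE = "none"


class When(str, enum.Enum):
    BEFORE_SPLIT = "before_split"
    AFTER_SPLIT = "after_split"


class SplitKind(str, enum.Enum):
    RANDOM = "random"
    GROUPED = "grouped"


@dataclass(frozen=True)
class OrderingPolicy:
    """Which transform to apply, and whether before or after the split."""

    transform: Transform = Transform.NONE
    when: When = When.AFTER_SPLIT


@dataclass
class SplitAssignment:
    """A partition of row indices into TRAIN/VAL/TEST."""

    subset_of: np.ndarray  # int array of Subset values, one per row
    ratios: tuple[float, float, float]
    grouped: bool = False
    group_key: str | None = None

    def indices(self, subset: Subset) -> np.ndarray:
        return np.flatnonzero(self.subset_of == int(subset))

    def sizes(self) -> tuple[int, int, int]:
        return tuple(int((self.subset_of == s).sum()) for s in Subset)  # type: ignore[return-value]

    def apply(self, table: LabeledTable) -> tuple[LabeledTable, LabeledTable, LabeledTable]:
        return tuple(table.take(self.indices(s)) for s in Subset)  # type: ignore[return-value]


def _check_ratios(ratios) -> tuple[float, float, float]:
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ConfigurationError("ratios must be three non-negative fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"ratios must sum to 1, got {sum(ratios)}")
    return ratios  # type: ignore[return-value]


def _largest_remainder(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Apportion n items to three subsets; exact and deterministic.

    Floors the quotas, then hands the leftover items to the subsets with the
    largest fractional remainders (ties: lower subset index first).
    """
    quotas = [n * r for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    return sizes


def split_random(
    table: LabeledTable, ratios=(0.6, 0.2, 0.2), seed: int = 0
) -> SplitAssignment:
    """Uniform random row-level partition (ignores patient grouping)."""
    ratios = _check_ratios(ratios)
    n = len(table)
    if n == 0:
        raise ConfigurationError("cannot split an empty table")
    sizes = _largest_remainder(n, ratios)
    perm = np.random.default_rng(seed).permutation(n)
    subset_of = np.empty(n, dtype=int)
    subset_of[perm[: sizes[0]]] = int(Subset.TRAIN)
    subset_of[perm[sizes[0] : sizes[0] + sizes[1]]] = int(Subset.VAL)
    subset_of[perm[sizes[0] + sizes[1] :]] = int(Subset.TEST)
    return SplitAssignment(subset_of=subset_of, ratios=ratios, grouped=False)


def split_grouped(
    table: LabeledTable,
    ratios=(0.6, 0.2, 0.2),
    group_key: str = "patient_id",
    seed: int = 0,
) -> SplitAssignment:
    """Group-coherent partition: all rows of a group land in one subset."""
    ratios = _check_ratios(ratios)
    if len(table) == 0:
        raise ConfigurationError("cannot split an empty table")
    if group_key not in ("patient_id", "provenance_id", "source_id"):
        raise ConfigurationError(f"unknown group_key {group_key!r}")
    values = getattr(table, group_key)
    if values is None:
        raise ConfigurationError(f"table has no {group_key} values")
    groups = np.unique(np.asarray(values, dtype=object).astype(str))
    n_subsets = sum(r > 0 for r in ratios)
    if len(groups) < n_subsets:
        raise InfeasibleSplitError(
            f"{len(groups)} groups cannot fill {n_subsets} subsets"
        )
    sizes = _largest_remainder(len(groups), ratios)
    # every nonzero-ratio subset must receive at least one group
    for i, r in enumerate(ratios):
        while r > 0 and sizes[i] == 0:
            j = int(np.argmax(sizes))
            sizes[j] -= 1
            sizes[i] += 1
    perm = np.random.default_rng(seed).permutation(len(groups))
    assignment = {}
    start = 0
    for subset, size in zip(Subset, sizes):
        for g in groups[perm[start : start + size]]:
            assignment[g] = int(subset)
        start += size
    subset_of = np.array([assignment[str(v)] for v in values], dtype=int)
    return SplitAssignment(
        subset_of=subset_of, ratios=ratios, grouped=True, group_key=group_key
    )


def oversample(table: LabeledTable, seed: int = 0) -> LabeledTable:
    """Balance classes by duplicating minority rows, sampled with replacement.

    Duplicates keep the origin row's ``provenance_id`` (and patient), so the
    auditor can detect copies that a later split scatters across subsets.
    Original rows are returned unchanged, in their original order.
    """
    neg, pos = table.class_counts()
    if neg == 0 or pos == 0:
        raise DegenerateDataError("oversampling needs both classes present")
    if neg == pos:
        return table
    minority = 1 if pos < neg else 0
    deficit = abs(neg - pos)
    minority_idx = np.flatnonzero(table.labels == minority)
    picks = np.random.default_rng(seed).choice(minority_idx, size=deficit, replace=True)
    dup = table.take(picks)
    dup.sample_id = np.array(
        [f"{sid}#dup{i}" for i, sid in enumerate(dup.sample_id)], dtype=object
    )
    # provenance_id stays that of the origin row (copied by take())
    return LabeledTable.concat([table, dup])


def augment(
    table: LabeledTable, copies_per_sample: int, jitter_sigma: float, seed: int = 0
) -> LabeledTable:
    """Append ``copies_per_sample`` jittered copies of every row.

    Copies add Gaussian noise of SD ``jitter_sigma`` to the features and
    inherit label, patient and provenance from the origin row.
    """
    if copies_per_sample < 0:
        raise ConfigurationError("copies_per_sample must be >= 0")
    if jitter_sigma < 0:
        raise ConfigurationError("jitter_sigma must be >= 0")
    if copies_per_sample == 0:
        return table
    rng = np.random.default_rng(seed)
    parts = [table]
    for c in range(copies_per_sample):
        copy = table.take(np.arange(len(table)))
        copy.features = copy.features + rng.normal(
            0.0, jitter_sigma, size=copy.features.shape
        )
        copy.sample_id = np.array(
            [f"{sid}#aug{c}" for sid in table.sample_id], dtype=object
        )
        parts.append(copy)
    return LabeledTable.concat(parts)


def feature_scores(table: LabeledTable) -> np.ndarray:
    """Absolute pooled-variance two-sample t statistic per feature.

    A feature with zero pooled variance scores ``inf`` if the class means
    differ (it separates the classes perfectly) and 0 otherwise.
    """
    neg, pos = table.class_counts()
    if neg == 0 or pos == 0:
        raise DegenerateDataError("feature scoring needs both classes present")
    x0 = table.features[table.labels == 0]
    x1 = table.features[table.labels == 1]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    v0 = x0.var(axis=0, ddof=1) if neg > 1 else np.zeros(table.n_features)
    v1 = x1.var(axis=0, ddof=1) if pos > 1 else np.zeros(table.n_features)
    dof = max(neg + pos - 2, 1)
    pooled = ((neg - 1) * v0 + (pos - 1) * v1) / dof
    denom = np.sqrt(pooled * (1.0 / neg + 1.0 / pos))
    diff = np.abs(m1 - m0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[(denom == 0) & (diff > 0)] = np.inf
    t[(denom == 0) & (diff == 0)] = 0.0
    return t


def select_top_features(table: LabeledTable, k: int) -> np.ndarray:
    """Indices of the k features with largest |t|, descending; ties to lower index."""
    if not 1 <= k <= table.n_features:
        raise ConfigurationError("k must lie in [1, n_features]")
    scores = feature_scores(table)
    order = np.lexsort((np.arange(table.n_features), -scores))
    return order[:k]


def leakage_audit(
    train: LabeledTable, val: LabeledTable, test: LabeledTable
) -> dict[str, int]:
    """Count provenance and patient identifiers appearing in >1 subset.

    Both counts are 0 exactly when the subsets are independent at the
    provenance level (no shared duplicated/augmented origins) and at the
    patient level (no patient spans subsets).
    """
    counts = {}
    for key in ("provenance_id", "patient_id"):
        sets = [set(getattr(t, key)) for t in (train, val, test)]
        spanning = (
            (sets[0] & sets[1]) | (sets[0] & sets[2]) | (sets[1] & sets[2])
        )
        counts[key] = len(spanning)
    return counts


def _apply_transform(
    table: LabeledTable,
    transform: Transform,
    seed: int,
    copies_per_sample: int,
    jitter_sigma: float,
    k_features: int | None,
) -> tuple[LabeledTable, np.ndarray | None]:
    if transform is Transform.OVERSAMPLE:
        return oversample(table, seed=seed), None
    if transform is Transform.AUGMENT:
        return augment(table, copies_per_sample, jitter_sigma, seed=seed), None
    if transform is Transform.SELECT_FEATURES:
        if k_features is None:
            raise ConfigurationError("SELECT_FEATURES requires k_features")
        idx = select_top_features(table, k_features)
        return table.select_features(idx), idx
    return table, None


def materialize(
    table: LabeledTable,
    policy: OrderingPolicy,
    split_kind: SplitKind = SplitKind.RANDOM,
    ratios=(0.6, 0.2, 0.2),
    seed: int = 0,
    copies_per_sample: int = 1,
    jitter_sigma: float = 0.1,
    k_features: int | None = None,
    group_key: str = "patient_id",
) -> tuple[LabeledTable, LabeledTable, LabeledTable, dict[str, int]]:
    """Run the split + transform pipeline in the order the policy dictates.

    Returns ``(train, val, test, audit)``.  ``BEFORE_SPLIT`` applies the
    transform to the full table and then splits it — the leak-prone order.
    ``AFTER_SPLIT`` splits first and applies the transform to the training
    rows only; for feature selection, the indices chosen on the training rows
    are then used to project validation and test.
    """

    def _split(t: LabeledTable) -> SplitAssignment:
        if split_kind is SplitKind.GROUPED:
            return split_grouped(t, ratios, group_key=group_key, seed=seed)
        return split_random(t, ratios, seed=seed)

    if policy.transform is Transform.NONE:
        train, val, test = _split(table).apply(table)
    elif policy.when is When.BEFORE_SPLIT:
        transformed, _ = _apply_transform(
            table, policy.transform, seed, copies_per_sample, jitter_sigma, k_features
        )
        train, val, test = _split(transformed).apply(transformed)
    else:
        train, val, test = _split(table).apply(table)
        train, selected = _apply_transform(
            train, policy.transform, seed, copies_per_sample, jitter_sigma, k_features
        )
        if selected is not None:
            val = val.select_features(selected)
            test = test.select_features(selected)
    return train, val, test, leakage_audit(train, val, test)
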