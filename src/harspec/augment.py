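"""Feature-space data augmentation: local averaging and per-class shuffling.

The augmentation ensemble builds three training variants from an original
feature set (OR):

* ``OR``              — the extracted features, untouched;
* ``OR + LA1``        — OR with first local averages (group size G1 = 4)
                        appended at the tail end;
* ``OR + LA1 + SH + LA2`` — OR+LA1 shuffled row-wise within each class,
                        with second local averages (G2 = 2) appended.

Local averaging takes consecutive non-overlapping groups of G same-class
rows (in current row order) and appends their element-wise mean as one new
row; leftover rows (< G) contribute no averaged row but stay in the set.
Shuffling permutes rows within each class only, so per-class counts and
row multisets are invariant.  Averaging shrinks per-column variance by
roughly 1/G, which is the mechanism that regularises training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureSet

__all__ = [
    "AugmentationSpec",
    "local_average",
    "shuffle_rows",
    "augment_or_la1",
    "augment_full",
    "expected_size_la1",
    "expected_size_full",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Group sizes and shuffle seed defining the augmentation ensemble."""

    G1: int = 4
    G2: int = 2
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.G1 < 2 or self.G2 < 2:
            raise ValueError("group sizes G1 and G2 must be >= 2")


def _class_order(labels: np.ndarray) -> list[str]:
    order: list[str] = []
    for lab in labels:
        if lab not in order:
            order.append(str(lab))
    return order


def local_average(fs: FeatureSet, G: int) -> FeatureSet:
    """Element-wise means of consecutive same-class groups of G rows.

    Returns the new averaged rows only (labels inherited from the group);
    the output has Σ_classes floor(n_class / G) rows.  Grouping follows
    the current row order within each class; a trailing remainder of
    fewer than G rows is dropped.
    """
    if G < 2:
        raise ValueError("G must be >= 2")
    rows = []
    labels = []
    for cls in _class_order(fs.labels):
        block = fs.X[fs.labels == cls]
        n_groups = block.shape[0] // G
        for g in range(n_groups):
            rows.append(block[g * G:(g + 1) * G].mean(axis=0))
            labels.append(cls)
    if not rows:
        return FeatureSet(X=np.empty((0, fs.n_features)),
                          labels=np.empty((0,), dtype=fs.labels.dtype),
                          provenance="LA")
    return FeatureSet(X=np.stack(rows), labels=np.asarray(labels), provenance="LA")


def shuffle_rows(fs: FeatureSet, seed: int) -> FeatureSet:
    """Permute rows independently within each class block.

    The row multiset and all per-class counts are unchanged; the
    permutation is deterministic given ``seed`` (one child generator per
    class, spawned in first-appearance class order).
    """
    ss = np.random.SeedSequence(seed)
    classes = _class_order(fs.labels)
    children = ss.spawn(len(classes))
    new_index = np.arange(len(fs))
    for cls, child in zip(classes, children):
        idx = np.flatnonzero(fs.labels == cls)
        rng = np.random.default_rng(child)
        new_index[idx] = idx[rng.permutation(len(idx))]
    prov = fs.provenance + "+SH" if not fs.provenance.endswith("+SH") else fs.provenance
    return FeatureSet(X=fs.X[new_index], labels=fs.labels[new_index], provenance=prov)


def augment_or_la1(fs: FeatureSet, spec: AugmentationSpec = AugmentationSpec()) -> FeatureSet:
    """OR rows followed by first local averages appended at the tail end."""
    if fs.provenance != "OR":
        raise ValueError(f"expected an OR feature set, got provenance {fs.provenance!r}")
    la1 = local_average(fs, spec.G1)
    return FeatureSet(X=np.vstack([fs.X, la1.X]),
                      labels=np.concatenate([fs.labels, la1.labels]),
                      provenance="OR+LA1")


def augment_full(fs: FeatureSet, spec: AugmentationSpec = AugmentationSpec()) -> FeatureSet:
    """Full ensemble: OR+LA1, per-class shuffle, second local averages.

    The shuffle applies to the whole OR+LA1 set (originals plus first
    averages) before the G2 grouping, so the second averages mix original
    and first-average rows.  Output size is
    ``|OR+LA1| + Σ_classes floor(n'_class / G2)``.
    """
    la1_set = augment_or_la1(fs, spec)
    shuffled = shuffle_rows(la1_set, spec.shuffle_seed)
    la2 = local_average(shuffled, spec.G2)
    return FeatureSet(X=np.vstack([shuffled.X, la2.X]),
                      labels=np.concatenate([shuffled.labels, la2.labels]),
                      provenance="OR+LA1+SH+LA2")


def expected_size_la1(class_counts: dict[str, int], G1: int = 4) -> int:
    """Closed-form |OR+LA1| from per-class OR counts."""
    n = sum(class_counts.values())
    return n + sum(c // G1 for c in class_counts.values())


def expected_size_full(class_counts: dict[str, int], G1: int = 4, G2: int = 2) -> int:
    """Closed-form |OR+LA1+SH+LA2| from per-class OR counts."""
    la1_counts = {k: c + c // G1 for k, c in class_counts.items()}
    return sum(la1_counts.values()) + sum(c // G2 for c in la1_counts.values())
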