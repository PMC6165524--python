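"""Bundled reference confusion matrices for three-activity recognition.

Fixed 3×3 count matrices (rows = true ST/SI/WA, columns = predicted) from
wrist-worn-IMU activity-recognition experiments, indexed by training
variant and learning rate.  Variants cover the 100- and 200-feature
spectral datasets (unaugmented ``or-*``, first-local-average ``la1-*``,
full-ensemble ``full-100``) and the public UCI-HAR three-activity extract
(``uci-or``, ``uci-la1``).  They serve as fixed inputs to the metric
arithmetic in :mod:`harspec.evaluate` — accuracies, precision/recall/f1
and accuracy improvements between augmented and unaugmented variants —
and as CLI/test fixtures that need no training run.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ConfusionMatrix, DEFAULT_CLASSES

__all__ = ["REFERENCE_MATRICES", "LEARNING_RATES", "get_matrix", "variants"]

#: Learning rates the reference runs were trained at.
LEARNING_RATES = (0.0002, 0.006, 0.003, 0.015, 0.01)

_RAW: dict[str, dict[float, list[list[int]]]] = {
    # Unaugmented 100-feature spectral dataset.
    "or-100": {
        0.0002: [[441, 240, 0], [113, 560, 0], [0, 1, 700]],
        0.006: [[0, 681, 0], [0, 673, 0], [0, 2, 699]],
        0.003: [[409, 272, 0], [98, 575, 0], [0, 1, 700]],
        0.015: [[0, 0, 681], [0, 0, 673], [0, 0, 701]],
        0.01: [[0, 0, 681], [0, 0, 673], [0, 0, 701]],
    },
    # Unaugmented 200-feature spectral dataset.
    "or-200": {
        0.0002: [[547, 153, 0], [154, 1066, 0], [0, 0, 694]],
        0.006: [[550, 149, 1], [168, 1052, 0], [1, 0, 693]],
        0.003: [[555, 145, 0], [150, 1070, 0], [0, 0, 694]],
        0.015: [[81, 580, 39], [33, 1177, 10], [0, 0, 694]],
        0.01: [[13, 656, 31], [3, 1207, 10], [1, 0, 693]],
    },
    # 100-feature dataset with first local averages appended (G=4).
    "la1-100": {
        0.0002: [[437, 244, 0], [106, 567, 0], [0, 1, 700]],
        0.006: [[97, 584, 0], [18, 655, 0], [1, 0, 700]],
        0.003: [[416, 265, 0], [103, 570, 0], [0, 1, 700]],
        0.015: [[0, 681, 0], [0, 673, 0], [0, 1, 700]],
        0.01: [[0, 680, 1], [0, 673, 0], [0, 0, 701]],
    },
    # 100-feature dataset with the full ensemble (LA1, shuffle, LA2).
    "full-100": {
        0.0002: [[406, 273, 2], [91, 578, 4], [7, 2, 692]],
        0.006: [[0, 681, 0], [0, 678, 0], [0, 701, 0]],
        0.003: [[391, 289, 1], [102, 571, 0], [10, 0, 691]],
        0.015: [[0, 0, 681], [0, 0, 673], [0, 0, 701]],
        0.01: [[0, 681, 0], [0, 673, 0], [0, 8, 693]],
    },
    # 200-feature dataset with first local averages appended (G=4).
    "la1-200": {
        0.0002: [[578, 121, 1], [219, 1001, 0], [0, 0, 694]],
        0.006: [[223, 477, 0], [88, 1132, 0], [0, 0, 694]],
        0.003: [[537, 168, 0], [140, 1080, 0], [0, 0, 694]],
        0.015: [[56, 611, 33], [21, 1188, 11], [1, 0, 693]],
        0.01: [[56, 611, 33], [21, 1188, 11], [1, 0, 693]],
    },
    # UCI-HAR three-activity extract, original windows only.
    "uci-or": {
        0.0002: [[480, 48, 4], [145, 344, 2], [3, 0, 493]],
        0.006: [[532, 0, 0], [491, 0, 0], [496, 0, 0]],
        0.003: [[319, 210, 3], [325, 160, 6], [0, 4, 492]],
        0.015: [[0, 528, 4], [0, 486, 5], [0, 0, 496]],
        0.01: [[0, 530, 2], [0, 486, 5], [0, 2, 494]],
    },
    # UCI-HAR extract with first local averages appended (G=4).
    "uci-la1": {
        0.0002: [[455, 67, 10], [153, 337, 1], [0, 0, 496]],
        0.006: [[525, 0, 7], [485, 1, 5], [0, 0, 496]],
        0.003: [[471, 57, 4], [107, 383, 1], [0, 0, 496]],
        0.015: [[532, 0, 0], [491, 0, 0], [496, 0, 0]],
        0.01: [[532, 0, 0], [491, 0, 0], [496, 0, 0]],
    },
}

REFERENCE_MATRICES: dict[str, dict[float, ConfusionMatrix]] = {
    variant: {rate: ConfusionMatrix(np.asarray(m), DEFAULT_CLASSES)
              for rate, m in rates.items()}
    for variant, rates in _RAW.items()
}


def variants() -> tuple[str, ...]:
    return tuple(REFERENCE_MATRICES)


def get_matrix(variant: str, learning_rate: float) -> ConfusionMatrix:
    """Look up one reference confusion matrix."""
    try:
        return REFERENCE_MATRICES[variant][learning_rate]
    except KeyError as exc:
        raise KeyError(
            f"no reference matrix for variant {variant!r} at rate {learning_rate}"
        ) from exc
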