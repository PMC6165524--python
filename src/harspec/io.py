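"""Delimited-text readers and writers for every pipeline artefact.

Formats:

* stream CSV — columns ``t, ax, ay, az, gx, gy, gz, label``, one header
  row; a file may hold several streams separated by label changes;
* feature CSV — header ``Q1..Qd, label``, one row per feature vector,
  provenance and bookkeeping in a JSON sidecar ``<name>.meta.json``;
* confusion CSV — class-labelled rows and columns;
* UCI-HAR "Inertial Signals" dialect — one fixed-width text file per
  channel with 128 floats per row, plus an integer class-code file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationSpec
from .evaluate import ConfusionMatrix
from .features import AnalysisWindow, FeatureSet
from .simulate import ImuStream

__all__ = [
    "write_stream_csv",
    "read_imu_csv",
    "write_feature_csv",
    "read_feature_csv",
    "write_confusion_csv",
    "read_confusion_csv",
    "read_uci_inertial",
    "write_uci_fixture",
    "UCI_CHANNEL_FILES",
    "DEFAULT_UCI_LABEL_MAP",
]

logger = logging.getLogger(__name__)

STREAM_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "label"]

#: Channel file stems in the UCI "Inertial Signals" naming, axis order
#: matching ImuStream columns (total acceleration, then body gyroscope).
UCI_CHANNEL_FILES = ("total_acc_x", "total_acc_y", "total_acc_z",
                     "body_gyro_x", "body_gyro_y", "body_gyro_z")

#: Standard UCI-HAR class codes for the three activities kept here.
DEFAULT_UCI_LABEL_MAP = {1: "WA", 4: "SI", 5: "ST"}

UCI_SAMPLES_PER_ROW = 128


def write_stream_csv(streams: list[ImuStream], path: str | Path) -> None:
    """Concatenate labelled streams into one CSV with a time column.

    The time column restarts from 0 at each stream boundary only if
    labels differ; to keep boundaries recoverable, consecutive streams
    share one continuous time axis."""
    frames = []
    t0 = 0.0
    for s in streams:
        df = pd.DataFrame(s.data, columns=STREAM_COLUMNS[1:7])
        df.insert(0, "t", t0 + np.arange(s.n_samples) / s.fs)
        df["label"] = s.label
        frames.append(df)
        t0 = float(df["t"].iloc[-1]) + 1.0 / s.fs
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.9g")


def read_imu_csv(path: str | Path) -> list[ImuStream]:
    """Read labelled streams from CSV, splitting on label-change boundaries.

    The sampling frequency is inferred from the median timestamp delta.
    Raises on a malformed row (with its line number) or a non-monotone
    time column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != STREAM_COLUMNS:
        raise ValueError(
            f"{path}: header must be {','.join(STREAM_COLUMNS)}, got {list(df.columns)}")
    if df.empty:
        logger.warning("%s: empty data section", path)
        return []
    numeric = df[STREAM_COLUMNS[:7]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed numeric value at line {line}")
    t = numeric["t"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0

    labels = df["label"].astype(str).to_numpy()
    boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    streams = []
    for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, len(df)]):
        streams.append(ImuStream(
            data=numeric.iloc[lo:hi, 1:7].to_numpy(),
            fs=fs, label=str(labels[lo])))
    return streams


def write_feature_csv(fs: FeatureSet, path: str | Path,
                      spec: AugmentationSpec | None = None) -> None:
    """Write a FeatureSet (header ``Q1..Qd,label``) plus a JSON sidecar.

    The sidecar ``<path stem>.meta.json`` records provenance, per-class
    counts and — when given — the augmentation group sizes and seed.
    """
    path = Path(path)
    cols = [f"Q{i + 1}" for i in range(fs.n_features)]
    df = pd.DataFrame(fs.X, columns=cols)
    df["label"] = fs.labels
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "provenance": fs.provenance,
        "n_rows": len(fs),
        "n_features": fs.n_features,
        "class_counts": fs.class_counts(),
    }
    if spec is not None:
        meta.update({"G1": spec.G1, "G2": spec.G2, "shuffle_seed": spec.shuffle_seed})
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_feature_csv(path: str | Path) -> FeatureSet:
    """Read a FeatureSet CSV; provenance restored from the sidecar if present."""
    path = Path(path)
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    provenance = "OR"
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", "OR")
    X = df.drop(columns="label").to_numpy(dtype=float)
    return FeatureSet(X=X, labels=df["label"].astype(str).to_numpy(),
                      provenance=provenance)


def write_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, index_label="true\\predicted")


def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    classes = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != classes:
        raise ValueError(f"{path}: row and column class labels differ")
    return ConfusionMatrix(counts=df.to_numpy(dtype=int), classes=classes)


def _read_fixed_width_channel(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            values = line.split()
            if len(values) != UCI_SAMPLES_PER_ROW:
                raise ValueError(
                    f"{path}: row {lineno} has {len(values)} values, "
                    f"expected {UCI_SAMPLES_PER_ROW}")
            try:
                rows.append(np.asarray(values, dtype=float))
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno} is not numeric") from exc
    return np.stack(rows) if rows else np.empty((0, UCI_SAMPLES_PER_ROW))


def read_uci_inertial(directory: str | Path, subset: str = "train",
                      label_map: dict[int, str] | None = None,
                      fs: float = 50.0,
                      ) -> tuple[list[AnalysisWindow], int]:
    """Read UCI-HAR-style fixed-width inertial-signal windows.

    Expects ``<channel>_<subset>.txt`` for each of the six channels and a
    ``y_<subset>.txt`` file of integer class codes in ``directory``.
    Rows whose code is outside ``label_map`` (default keeps walking,
    sitting, standing) are dropped; returns the kept 128-sample 6-channel
    windows and the dropped-row count.
    """
    directory = Path(directory)
    label_map = DEFAULT_UCI_LABEL_MAP if label_map is None else label_map
    channels = []
    for stem in UCI_CHANNEL_FILES:
        mat = _read_fixed_width_channel(directory / f"{stem}_{subset}.txt")
        channels.append(mat)
    n_rows = channels[0].shape[0]
    for stem, mat in zip(UCI_CHANNEL_FILES, channels):
        if mat.shape[0] != n_rows:
            raise ValueError(
                f"channel {stem} has {mat.shape[0]} rows, expected {n_rows}")
    codes = np.loadtxt(directory / f"y_{subset}.txt", dtype=int, ndmin=1)
    if codes.shape[0] != n_rows:
        raise ValueError(
            f"label file has {codes.shape[0]} rows, channel files have {n_rows}")

    windows: list[AnalysisWindow] = []
    dropped = 0
    for r in range(n_rows):
        code = int(codes[r])
        if code not in label_map:
            dropped += 1
            continue
        data = np.column_stack([mat[r] for mat in channels])
        windows.append(AnalysisWindow(data=data, fs=fs, start_time=0.0,
                                      label=label_map[code]))
    if dropped:
        logger.info("dropped %d window(s) with labels outside %s",
                    dropped, sorted(label_map))
    return windows, dropped


def write_uci_fixture(directory: str | Path, windows: list[AnalysisWindow],
                      subset: str = "train",
                      label_codes: dict[str, int] | None = None) -> None:
    """Emit windows in the UCI inertial-signals dialect (fixture writer).

    Each channel file holds one fixed-width ``% .6e`` row of 128 samples
    per window; labels go to ``y_<subset>.txt`` as integer codes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if label_codes is None:
        label_codes = {v: k for k, v in DEFAULT_UCI_LABEL_MAP.items()}
    for w in windows:
        if w.n_samples != UCI_SAMPLES_PER_ROW:
            raise ValueError(
                f"UCI dialect requires {UCI_SAMPLES_PER_ROW}-sample windows, "
                f"got {w.n_samples}")
    for c, stem in enumerate(UCI_CHANNEL_FILES):
        with open(directory / f"{stem}_{subset}.txt", "w") as fh:
            for w in windows:
                fh.write(" ".join(f"{v: .6e}" for v in w.data[:, c]) + "\n")
    with open(directory / f"y_{subset}.txt", "w") as fh:
        for w in windows:
            fh.write(f"{label_codes[w.label]}\n")
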