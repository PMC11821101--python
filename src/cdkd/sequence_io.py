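"""Reading and writing frame sequences, labels, embeddings and results.

The on-disk conventions are package conventions (frames as PNG/TIFF/DICOM
directories, labels as ``frame_index,label`` CSV, embeddings as a delimited
numeric matrix with one row per frame, detection results as JSON); the
method itself only assumes an *ordered* sequence of same-shape grayscale
frames.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from cdkd.errors import InputError, ShapeError, ValidationError

__all__ = [
    "FrameSequence",
    "LabelVector",
    "KeyframeResult",
    "read_sequence",
    "write_sequence",
    "read_labels",
    "write_labels",
    "read_embeddings",
    "write_embeddings",
    "read_result",
    "write_result",
    "natural_sort_key",
]

_DIALECT_GLOBS = {
    "png": ("*.png", "*.PNG"),
    "tiff": ("*.tif", "*.tiff", "*.TIF", "*.TIFF"),
    "dicom": ("*.dcm", "*.DCM", "*.dicom"),
}


@dataclass
class FrameSequence:
    """An ordered stack of same-shape grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (N, H, W)
        Per-frame intensity arrays, values in ``[0, max_value]``.
    max_value : float
        Dynamic range L of the intensities (255 for 8-bit data).
    source_ids : list of str
        Per-frame identifiers (filenames or synthetic indices).
    """

    frames: np.ndarray
    max_value: float = 255.0
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ShapeError(
                f"frames must be a (N, H, W) stack, got ndim={self.frames.ndim}"
            )
        n = self.frames.shape[0]
        if n < 3:
            raise ValidationError(f"a sequence needs at least 3 frames, got {n}")
        if self.max_value <= 0:
            raise ValidationError(f"max_value must be positive, got {self.max_value}")
        lo = float(self.frames.min())
        hi = float(self.frames.max())
        if lo < 0 or hi > self.max_value:
            raise ValidationError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_value}]"
            )
        if not self.source_ids:
            self.source_ids = [str(i) for i in range(n)]
        if len(self.source_ids) != n:
            raise ValidationError(
                f"{len(self.source_ids)} source_ids for {n} frames"
            )

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


@dataclass
class LabelVector:
    """Per-frame binary keyframe labels (1 = extreme cardiac phase)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D vector")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValidationError(f"labels must be 0/1, found {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    @property
    def keyframe_indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.labels)]


@dataclass
class KeyframeResult:
    """Detected keyframes plus the candidate pairs that produced them."""

    keyframes: list[int]
    provenance: list  # list of CandidatePair
    parameters: dict

    def __post_init__(self) -> None:
        if list(self.keyframes) != sorted(set(int(k) for k in self.keyframes)):
            raise ValidationError("keyframes must be strictly increasing, no duplicates")
        endpoints = set()
        for p in self.provenance:
            endpoints.add(int(p.i))
            endpoints.add(int(p.j))
        missing = [k for k in self.keyframes if k not in endpoints]
        if self.provenance and missing:
            raise ValidationError(
                f"keyframes {missing} do not appear in any provenance pair"
            )


def natural_sort_key(name: str) -> tuple:
    """Numeric-aware sort key: ``f2 < f10`` because 2 < 10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # channel average per the package convention
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ShapeError(f"frame has unsupported ndim {arr.ndim}")
    return np.asarray(arr, dtype=np.float64)


def _max_value_for_dtype(dtype: np.dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 255.0


def _read_image_frame(path: Path) -> tuple[np.ndarray, float]:
    import imageio.v3 as iio

    arr = iio.imread(path)
    return _to_grayscale(arr), _max_value_for_dtype(arr.dtype)


def _read_dicom_frame(path: Path) -> tuple[np.ndarray, float, int | None]:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array)
    bits = int(getattr(ds, "BitsStored", 0) or 0)
    max_value = float(2**bits - 1) if bits else _max_value_for_dtype(arr.dtype)
    instance = getattr(ds, "InstanceNumber", None)
    return _to_grayscale(arr), max_value, (int(instance) if instance is not None else None)


def _infer_dialect(directory: Path) -> str:
    for dialect, globs in _DIALECT_GLOBS.items():
        if any(any(directory.glob(g)) for g in globs):
            return dialect
    raise InputError(f"no PNG/TIFF/DICOM frames found in {directory}")


def read_sequence(path: str | Path, dialect: str | None = None) -> FrameSequence:
    """Read an ordered grayscale frame sequence from a directory.

    Frames are ordered by a numeric-aware sort of their filenames; DICOM
    series are ordered by ``InstanceNumber`` when every file carries one.
    Multi-channel images are averaged to a single channel.

    Parameters
    ----------
    path : path-like
        Directory containing the frames.
    dialect : {"png", "tiff", "dicom"}, optional
        File format; inferred from the directory contents when omitted.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    if dialect is None:
        dialect = _infer_dialect(directory)
    if dialect not in _DIALECT_GLOBS:
        raise InputError(f"unknown dialect {dialect!r}")
    files: list[Path] = []
    for g in _DIALECT_GLOBS[dialect]:
        files.extend(directory.glob(g))
    files = sorted(set(files), key=lambda p: natural_sort_key(p.name))
    if len(files) < 3:
        raise InputError(
            f"{directory} contains {len(files)} {dialect} frames; need at least 3"
        )

    frames: list[np.ndarray] = []
    max_value = 0.0
    if dialect == "dicom":
        entries = []
        for f in files:
            arr, mv, instance = _read_dicom_frame(f)
            entries.append((instance, f, arr, mv))
        if all(e[0] is not None for e in entries):
            entries.sort(key=lambda e: (e[0], natural_sort_key(e[1].name)))
        ordered = [(f, arr, mv) for _, f, arr, mv in entries]
    else:
        ordered = []
        for f in files:
            arr, mv = _read_image_frame(f)
            ordered.append((f, arr, mv))

    shape0 = ordered[0][1].shape
    ids = []
    for f, arr, mv in ordered:
        if arr.shape != shape0:
            raise ShapeError(
                f"frame {f.name} has shape {arr.shape}, expected {shape0}"
            )
        frames.append(arr)
        max_value = max(max_value, mv)
        ids.append(f.name)
    return FrameSequence(np.stack(frames), max_value=max_value, source_ids=ids)


def write_sequence(seq: FrameSequence, path: str | Path, force: bool = False) -> list[Path]:
    """Write frames as zero-padded 8/16-bit PNGs; returns written paths."""
    import imageio.v3 as iio

    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    existing = list(directory.glob("*.png"))
    if existing and not force:
        raise InputError(f"{directory} already contains PNG frames; pass force=True")
    dtype = np.uint8 if seq.max_value <= 255 else np.uint16
    width = max(4, len(str(len(seq) - 1)))
    written = []
    for t in range(len(seq)):
        out = directory / f"frame_{t:0{width}d}.png"
        iio.imwrite(out, np.round(seq.frames[t]).astype(dtype))
        written.append(out)
    return written


def read_labels(path: str | Path, n_frames: int | None = None) -> LabelVector:
    """Read per-frame binary labels from a ``frame_index,label`` CSV."""
    import pandas as pd

    p = Path(path)
    if not p.is_file():
        raise InputError(f"label file not found: {p}")
    df = pd.read_csv(p)
    required = {"frame_index", "label"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"label CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    idx = df["frame_index"].to_numpy()
    n = len(df)
    if sorted(idx.tolist()) != list(range(n)):
        raise ValidationError("frame_index must cover 0..N-1 with no gaps")
    labels = np.zeros(n, dtype=np.int64)
    labels[idx] = df["label"].to_numpy()
    vec = LabelVector(labels)
    if n_frames is not None and len(vec) != n_frames:
        raise ValidationError(f"{len(vec)} labels for a {n_frames}-frame sequence")
    return vec


def write_labels(labels: LabelVector, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"frame_index": np.arange(len(labels)), "label": labels.labels}
    ).to_csv(path, index=False)


def _sniff_delimiter(first_line: str) -> str | None:
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return None  # whitespace


def read_embeddings(path: str | Path, n_frames: int | None = None) -> np.ndarray:
    """Read an N×d embedding matrix from delimited text (CSV/TSV/whitespace).

    Row ``i`` is the feature vector of frame ``i`` — e.g. a flattened
    18×512 w+-space latent code (d = 9216) saved by an external encoder.
    """
    p = Path(path)
    if not p.is_file():
        raise InputError(f"embedding file not found: {p}")
    with open(p) as fh:
        first = fh.readline()
    if not first.strip():
        raise InputError(f"embedding file is empty: {p}")
    delim = _sniff_delimiter(first)
    try:
        mat = np.loadtxt(p, delimiter=delim, ndmin=2, dtype=np.float64)
    except ValueError as exc:  # ragged rows or non-numeric cells
        raise ValidationError(f"cannot parse embedding matrix {p}: {exc}") from exc
    if n_frames is not None and mat.shape[0] != n_frames:
        raise ValidationError(
            f"embedding matrix has {mat.shape[0]} rows for a {n_frames}-frame sequence"
        )
    return mat


def write_embeddings(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=np.float64), delimiter=",", fmt="%.17g")


def write_result(result: KeyframeResult, path: str | Path) -> None:
    """Serialize a detection result as JSON."""
    payload = {
        "keyframes": [int(k) for k in result.keyframes],
        "provenance": [
            {"i": int(p.i), "j": int(p.j), "value": float(p.value)}
            for p in result.provenance
        ],
        "parameters": result.parameters,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_result(path: str | Path) -> KeyframeResult:
    from cdkd.keyframe_detection import CandidatePair

    p = Path(path)
    if not p.is_file():
        raise InputError(f"result file not found: {p}")
    payload = json.loads(p.read_text())
    pairs = [
        CandidatePair(int(d["i"]), int(d["j"]), float(d["value"]))
        for d in payload.get("provenance", [])
    ]
    return KeyframeResult(
        keyframes=[int(k) for k in payload["keyframes"]],
        provenance=pairs,
        parameters=payload.get("parameters", {}),
    )
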