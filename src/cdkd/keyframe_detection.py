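"""Heartbeat-keyframe detection on the inter-frame comparison matrix.

The pipeline: embed each frame (for the cosine metric), fill the N×N
pairwise matrix, find cells that are windowed local extrema — strictly
more extreme than every other cell within Chebyshev distance
``window_radius`` of the full symmetric matrix — and run non-extremum
suppression over the resulting candidate frame pairs.  A candidate cell
``(i, j)`` names two frames that plausibly sit at opposite poles of the
cardiac cycle (maximal vasodilation vs. vasoconstriction), because the
two most different frames of a heartbeat are the two extreme-phase ones.

Only upper-triangle cells with ``j - i >= min_separation`` can become
candidates: the matrix is symmetric (the mirrored cell is the same
event) and a systole/diastole pair cannot be near-adjacent frames.  The
neighbour window, however, always reads the full symmetric matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from cdkd.embeddings import BackendSpec, EmbeddingMatrix, embed
from cdkd.errors import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    ValidationError,
)
from cdkd.frame_metrics import MetricSpec, SsimConstants, l1_distance, psnr, ssim_global
from cdkd.sequence_io import FrameSequence, KeyframeResult

__all__ = [
    "PairwiseMatrix",
    "CandidatePair",
    "DetectorParams",
    "build_matrix",
    "find_local_extrema",
    "suppress",
    "detect",
    "export_matrix",
    "import_matrix",
]


@dataclass
class PairwiseMatrix:
    """Symmetric N×N matrix of inter-frame comparison values."""

    values: np.ndarray
    orientation: Literal["similarity", "difference"]
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"pairwise matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, rtol=0.0, atol=1e-9, equal_nan=True):
            raise ValidationError("pairwise matrix must be symmetric")
        if self.orientation not in ("similarity", "difference"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True, order=True)
class CandidatePair:
    """A local-extremum cell (i, j) of the pairwise matrix, i < j."""

    i: int
    j: int
    value: float

    def __post_init__(self) -> None:
        if not (0 <= self.i < self.j):
            raise ValidationError(f"need 0 <= i < j, got ({self.i}, {self.j})")


@dataclass(frozen=True)
class DetectorParams:
    """Tunable knobs of the detector.

    ``window_radius`` is the Chebyshev radius of the local-extremum
    window ("adjacent points within a distance of 2" → a 5×5
    neighbourhood); ``min_separation`` is both the diagonal exclusion
    band for candidate cells and the suppression distance (frames closer
    than this to an accepted keyframe are skipped).
    """

    window_radius: int = 2
    min_separation: int = 2
    metric: MetricSpec = field(default_factory=lambda: MetricSpec("cosine"))
    backend: BackendSpec = field(default_factory=BackendSpec)

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ConfigurationError("window_radius must be >= 1")
        if self.min_separation < 1:
            raise ConfigurationError("min_separation must be >= 1")


def _finite_cap(values: np.ndarray) -> np.ndarray:
    """Replace +inf cells by (finite max + 1): keeps the matrix
    exportable while never creating a spurious minimum."""
    if not np.isinf(values).any():
        return values
    finite = values[np.isfinite(values)]
    cap = float(finite.max()) + 1.0 if finite.size else 1.0
    out = values.copy()
    out[np.isposinf(out)] = cap
    return out


def build_matrix(data: FrameSequence | EmbeddingMatrix, params: DetectorParams) -> PairwiseMatrix:
    """Fill the symmetric all-pairs comparison matrix for one metric.

    ``data`` is a FrameSequence for pixel metrics; for the cosine metric
    it may be either a FrameSequence (embedded via ``params.backend``)
    or an already-computed EmbeddingMatrix.
    """
    spec = params.metric
    if spec.domain == "embedding":
        if isinstance(data, FrameSequence):
            emb = embed(data, params.backend)
        elif isinstance(data, EmbeddingMatrix):
            emb = data
        else:
            raise ConfigurationError(
                f"cosine metric needs a sequence or embedding matrix, got {type(data).__name__}"
            )
        rows = emb.values
        norms = np.linalg.norm(rows, axis=1)
        zero = np.flatnonzero(norms == 0.0)
        if zero.size:
            raise DegenerateInputError(
                f"frame {int(zero[0])} has a zero-norm embedding; cosine is undefined"
            )
        unit = rows / norms[:, None]
        values = np.clip(unit @ unit.T, -1.0, 1.0)
        np.fill_diagonal(values, spec.self_value)
        values = (values + values.T) / 2.0
        return PairwiseMatrix(values, orientation=spec.orientation, metric_name=spec.name)

    if not isinstance(data, FrameSequence):
        raise ConfigurationError(
            f"metric {spec.name!r} needs a FrameSequence, got {type(data).__name__}"
        )
    n = len(data)
    values = np.zeros((n, n), dtype=np.float64)
    mv = data.max_value
    consts = SsimConstants(L=mv)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = data.frames[i], data.frames[j]
            if spec.name == "l1":
                v = l1_distance(x, y)
            elif spec.name == "psnr":
                v = psnr(x, y, max_value=mv)
            else:
                v = ssim_global(x, y, consts)
            values[i, j] = values[j, i] = v
    np.fill_diagonal(values, spec.self_value)
    values = _finite_cap(values)
    return PairwiseMatrix(values, orientation=spec.orientation, metric_name=spec.name)


def find_local_extrema(
    M: PairwiseMatrix,
    window_radius: int = 2,
    min_separation: int = 2,
    require_full_window: bool = False,
) -> list[CandidatePair]:
    """Windowed strict local extrema of the pairwise matrix.

    A cell qualifies iff its value is strictly more extreme (smaller for
    similarity orientation, larger for difference) than every other cell
    of the full symmetric matrix within Chebyshev distance
    ``window_radius``, the window clipped at the matrix borders.  With
    ``require_full_window=True`` border cells are excluded entirely:
    only cells whose whole (2r+1)² window lies inside the matrix can
    qualify.  (:func:`detect` uses this mode — a cell at the matrix
    border compares against a truncated window, so a sequence that ends
    while still approaching a cardiac pole would otherwise always yield
    a spurious detection at its last frames.)  Candidates are restricted
    to upper-triangle cells with ``j - i >= min_separation`` and
    returned most-extreme-first (ties broken by (i, j)).  Plateaus yield
    no candidates.
    """
    if window_radius < 1 or min_separation < 1:
        raise ConfigurationError("window_radius and min_separation must be >= 1")
    v = M.values
    n = M.n
    k = 2 * window_radius + 1
    footprint = np.ones((k, k), dtype=bool)
    footprint[window_radius, window_radius] = False  # neighbours only
    if M.orientation == "similarity":
        neigh = ndimage.minimum_filter(v, footprint=footprint, mode="constant", cval=math.inf)
        is_ext = v < neigh
    else:
        neigh = ndimage.maximum_filter(v, footprint=footprint, mode="constant", cval=-math.inf)
        is_ext = v > neigh
    if require_full_window:
        r = window_radius
        interior = np.zeros_like(is_ext)
        if n > 2 * r:
            interior[r : n - r, r : n - r] = True
        is_ext &= interior
    cands: list[CandidatePair] = []
    ii, jj = np.nonzero(is_ext)
    for i, j in zip(ii.tolist(), jj.tolist()):
        if j - i >= min_separation:
            cands.append(CandidatePair(i, j, float(v[i, j])))
    sign = 1.0 if M.orientation == "similarity" else -1.0
    cands.sort(key=lambda c: (sign * c.value, c.i, c.j))
    return cands


def suppress(
    cands: list[CandidatePair],
    orientation: Literal["similarity", "difference"],
    min_separation: int = 2,
    parameters: dict | None = None,
) -> KeyframeResult:
    """Non-extremum suppression over candidate frame pairs.

    Pairs are processed most-extreme-first (ascending value for
    similarity orientation, descending for difference; ties by (i, j)).
    Each endpoint frame is accepted iff its index distance to every
    already-accepted frame is at least ``min_separation``; closer frames
    are skipped.  Both endpoints of the first pair are always accepted.
    """
    if min_separation < 1:
        raise ConfigurationError("min_separation must be >= 1")
    sign = 1.0 if orientation == "similarity" else -1.0
    ordered = sorted(cands, key=lambda c: (sign * c.value, c.i, c.j))
    accepted: list[int] = []
    provenance: list[CandidatePair] = []
    for pair in ordered:
        used = False
        for frame in (pair.i, pair.j):
            if all(abs(frame - a) >= min_separation for a in accepted):
                accepted.append(frame)
                used = True
        if used:
            provenance.append(pair)
    return KeyframeResult(
        keyframes=sorted(accepted),
        provenance=provenance,
        parameters=dict(parameters or {}),
    )


def detect(
    seq: FrameSequence | EmbeddingMatrix, params: DetectorParams | None = None
) -> KeyframeResult:
    """Run the full pipeline: embed → matrix → local extrema → suppression."""
    params = params if params is not None else DetectorParams()
    M = build_matrix(seq, params)
    # full-window rule: sequence ends cannot certify an extremum
    cands = find_local_extrema(
        M, params.window_radius, params.min_separation, require_full_window=True
    )
    meta = {
        "metric": params.metric.name,
        "backend": params.backend.name,
        "window_radius": params.window_radius,
        "min_separation": params.min_separation,
    }
    return suppress(cands, M.orientation, params.min_separation, parameters=meta)


def export_matrix(M: PairwiseMatrix, path: str | Path) -> None:
    """Write the matrix as CSV with a frame-index header row and column."""
    import pandas as pd

    df = pd.DataFrame(
        M.values, index=np.arange(M.n), columns=np.arange(M.n)
    )
    df.to_csv(path, float_format="%.17g")


def import_matrix(
    path: str | Path,
    orientation: Literal["similarity", "difference"] = "similarity",
    metric_name: str = "",
) -> PairwiseMatrix:
    """Read back a matrix written by :func:`export_matrix`."""
    import pandas as pd

    p = Path(path)
    if not p.is_file():
        raise InputError(f"matrix file not found: {p}")
    df = pd.read_csv(p, index_col=0)
    return PairwiseMatrix(df.to_numpy(dtype=np.float64), orientation=orientation, metric_name=metric_name)
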