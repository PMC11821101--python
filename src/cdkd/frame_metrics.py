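"""Inter-frame comparison functions.

Four comparators are provided.  ``cosine`` operates on per-frame feature
vectors (embedding domain); ``l1``, ``psnr`` and ``ssim`` operate on the
raw pixel arrays.  Cosine, PSNR and SSIM are *similarity* measures (a
keyframe pair is a windowed local minimum of the pairwise matrix); L1 is
a *difference* measure (a keyframe pair is a local maximum).

SSIM here is the single global-window statistic

    SSIM(x, y) = (2 μx μy + C1)(2 σxy + C2)
                 / ((μx² + μy² + C1)(σx² + σy² + C2))

with means, variances and covariance taken over the whole frame
(population convention, 1/n), C1 = (K1 L)², C2 = (K2 L)².  The common
11×11 Gaussian-windowed mean-SSIM is deliberately not used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from cdkd.errors import ConfigurationError, DegenerateInputError, ShapeError

__all__ = [
    "MetricSpec",
    "SsimConstants",
    "cosine_similarity",
    "l1_distance",
    "psnr",
    "ssim_global",
    "compare_frames",
    "METRIC_NAMES",
]

METRIC_NAMES = ("cosine", "l1", "psnr", "ssim")

_ORIENTATION = {"cosine": "similarity", "l1": "difference", "psnr": "similarity", "ssim": "similarity"}
_DOMAIN = {"cosine": "embedding", "l1": "pixel", "psnr": "pixel", "ssim": "pixel"}


@dataclass(frozen=True)
class MetricSpec:
    """Names a comparator and fixes its orientation and input domain.

    ``orientation`` says where keyframe pairs live in the pairwise
    matrix: minima for similarity metrics (cosine, PSNR, SSIM), maxima
    for difference metrics (L1).
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise ConfigurationError(
                f"unknown metric {self.name!r}; choose from {METRIC_NAMES}"
            )

    @property
    def orientation(self) -> Literal["similarity", "difference"]:
        return _ORIENTATION[self.name]

    @property
    def domain(self) -> Literal["embedding", "pixel"]:
        return _DOMAIN[self.name]

    @property
    def self_value(self) -> float:
        """Value of comparing a frame with itself."""
        return {"cosine": 1.0, "ssim": 1.0, "l1": 0.0, "psnr": math.inf}[self.name]


@dataclass(frozen=True)
class SsimConstants:
    """Stabilisation constants C1=(K1·L)², C2=(K2·L)² for global SSIM."""

    K1: float = 0.01
    K2: float = 0.03
    L: float = 255.0

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0 or self.L <= 0:
            raise ConfigurationError("K1, K2 and L must all be positive")

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2


def _check_same_shape(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def cosine_similarity(f_i: np.ndarray, f_j: np.ndarray) -> float:
    """Cosine of the angle between two feature vectors, in [-1, 1].

    Raises :class:`DegenerateInputError` on a zero-norm vector rather
    than silently returning NaN.
    """
    u, v = _check_same_shape(np.ravel(f_i), np.ravel(f_j))
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise DegenerateInputError("cosine similarity undefined for a zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def l1_distance(x: np.ndarray, y: np.ndarray, normalize: bool = False) -> float:
    """Sum of absolute per-pixel differences (mean if ``normalize``)."""
    x, y = _check_same_shape(x, y)
    total = float(np.abs(x - y).sum())
    return total / x.size if normalize else total


def psnr(x: np.ndarray, y: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical frames."""
    if max_value <= 0:
        raise ConfigurationError(f"max_value must be positive, got {max_value}")
    x, y = _check_same_shape(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / mse)


def ssim_global(x: np.ndarray, y: np.ndarray, constants: SsimConstants | None = None) -> float:
    """Structural similarity over a single whole-frame window."""
    x, y = _check_same_shape(x, y)
    if x.size < 2:
        raise ShapeError("global SSIM needs at least 2 pixels")
    c = constants if constants is not None else SsimConstants()
    mu_x = float(x.mean())
    mu_y = float(y.mean())
    # population (1/n) moments: the constant-frame closed form is exact
    var_x = float(np.mean((x - mu_x) ** 2))
    var_y = float(np.mean((y - mu_y) ** 2))
    cov = float(np.mean((x - mu_x) * (y - mu_y)))
    num = (2 * mu_x * mu_y + c.C1) * (2 * cov + c.C2)
    den = (mu_x**2 + mu_y**2 + c.C1) * (var_x + var_y + c.C2)
    return num / den


def compare_frames(data, i: int, j: int, spec: MetricSpec, max_value: float = 255.0) -> float:
    """Uniform dispatch: compare frames ``i`` and ``j`` under ``spec``.

    ``data`` is a :class:`~cdkd.sequence_io.FrameSequence` for pixel
    metrics, or an N×d embedding matrix (ndarray or
    :class:`~cdkd.embeddings.EmbeddingMatrix`) for cosine.
    """
    from cdkd.embeddings import EmbeddingMatrix
    from cdkd.sequence_io import FrameSequence

    if spec.domain == "embedding":
        if isinstance(data, EmbeddingMatrix):
            rows = data.values
        elif isinstance(data, np.ndarray) and data.ndim == 2:
            rows = data
        else:
            raise ConfigurationError(
                f"metric {spec.name!r} needs an embedding matrix, got {type(data).__name__}"
            )
        return cosine_similarity(rows[i], rows[j])

    if not isinstance(data, FrameSequence):
        raise ConfigurationError(
            f"metric {spec.name!r} needs a FrameSequence, got {type(data).__name__}"
        )
    x, y = data.frames[i], data.frames[j]
    mv = data.max_value
    if spec.name == "l1":
        return l1_distance(x, y)
    if spec.name == "psnr":
        return psnr(x, y, max_value=mv)
    return ssim_global(x, y, SsimConstants(L=mv))
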