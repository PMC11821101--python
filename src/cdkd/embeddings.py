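"""Frame-to-feature-vector backends.

The detection algorithm only needs one real vector per frame.  In the
clinical setting those vectors are w+-space latent codes produced by a
pretrained GAN-inversion encoder (18 style vectors of length 512,
flattened to 9216 dimensions); that encoder is GPU-scale pretrained
machinery and is consumed here purely through the ``external`` backend,
which loads its saved codes from a delimited text file.  Three
self-contained backends — raw flattening, block-mean downsampling and
per-sequence PCA — cover desk-scale use and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from cdkd.errors import ConfigurationError, ValidationError
from cdkd.sequence_io import FrameSequence, read_embeddings

__all__ = [
    "EmbeddingMatrix",
    "BackendSpec",
    "embed",
    "embed_flatten",
    "embed_downsample",
    "embed_pca",
    "BACKEND_NAMES",
]

BACKEND_NAMES = ("flatten", "downsample", "pca", "external")


@dataclass
class EmbeddingMatrix:
    """N×d matrix whose row ``i`` is the feature vector of frame ``i``."""

    values: np.ndarray
    backend_name: str = "external"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("embedding matrix must be 2-D (N×d)")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def d(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class BackendSpec:
    """Configuration for one embedding backend.

    Parameters
    ----------
    name : {"flatten", "downsample", "pca", "external"}
    downsample_factor : int
        Block size for the block-mean backend (default 8).
    pca_components : int
        Number of principal components to keep (default 32).
    external_path : path-like, optional
        Delimited text file of precomputed per-frame vectors; required
        for the ``external`` backend.
    seed : int
        Random seed forwarded to stochastic backends (PCA uses a
        deterministic full SVD, so the seed only fixes the solver).
    """

    name: str = "flatten"
    downsample_factor: int = 8
    pca_components: int = 32
    external_path: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BACKEND_NAMES:
            raise ConfigurationError(
                f"unknown backend {self.name!r}; choose from {BACKEND_NAMES}"
            )
        if self.downsample_factor < 1:
            raise ConfigurationError("downsample_factor must be >= 1")
        if self.pca_components < 1:
            raise ConfigurationError("pca_components must be >= 1")
        if self.name == "external" and self.external_path is None:
            raise ConfigurationError("external backend requires external_path")


def embed_flatten(seq: FrameSequence) -> EmbeddingMatrix:
    """Row-major flattening of each frame; d = H·W."""
    n = len(seq)
    return EmbeddingMatrix(seq.frames.reshape(n, -1).copy(), backend_name="flatten")


def embed_downsample(seq: FrameSequence, factor: int = 8) -> EmbeddingMatrix:
    """Non-overlapping ``factor``×``factor`` block means, then flattened.

    Trailing partial blocks are averaged over their actual size, so
    d = ⌈H/factor⌉·⌈W/factor⌉.
    """
    h, w = seq.frame_shape
    if factor < 1:
        raise ConfigurationError("factor must be >= 1")
    if factor > min(h, w):
        raise ConfigurationError(
            f"factor {factor} exceeds the smaller frame dimension {min(h, w)}"
        )
    row_edges = np.arange(0, h, factor)
    col_edges = np.arange(0, w, factor)
    row_counts = np.diff(np.append(row_edges, h)).astype(np.float64)
    col_counts = np.diff(np.append(col_edges, w)).astype(np.float64)
    # sum over blocks via reduceat on each axis, then divide by true counts
    sums = np.add.reduceat(np.add.reduceat(seq.frames, row_edges, axis=1), col_edges, axis=2)
    means = sums / (row_counts[None, :, None] * col_counts[None, None, :])
    return EmbeddingMatrix(means.reshape(len(seq), -1), backend_name="downsample")


def embed_pca(seq: FrameSequence, components: int = 32, seed: int = 0) -> EmbeddingMatrix:
    """Per-sequence PCA scores of the flattened, mean-centred frames.

    The projection is fit on the sequence itself (no persisted model),
    using a full SVD with the sign convention that each component's
    largest-magnitude loading is positive, so results are deterministic.
    """
    from sklearn.decomposition import PCA

    n = len(seq)
    flat_dim = seq.frames[0].size
    if components > min(n, flat_dim):
        raise ConfigurationError(
            f"components={components} exceeds min(N={n}, H*W={flat_dim})"
        )
    flat = seq.frames.reshape(n, -1)
    pca = PCA(n_components=components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(flat)
    return EmbeddingMatrix(scores, backend_name="pca")


def embed(seq: FrameSequence, spec: BackendSpec) -> EmbeddingMatrix:
    """Dispatch to the backend named in ``spec``."""
    if spec.name == "flatten":
        return embed_flatten(seq)
    if spec.name == "downsample":
        return embed_downsample(seq, spec.downsample_factor)
    if spec.name == "pca":
        return embed_pca(seq, spec.pca_components, spec.seed)
    mat = read_embeddings(spec.external_path, n_frames=len(seq))
    return EmbeddingMatrix(mat, backend_name="external")
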