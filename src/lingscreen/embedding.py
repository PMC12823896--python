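"""Transcript embeddings, truncated SVD, and the ``emb_1`` projection.

Each transcript is embedded as a dense vector; stacking the training
transcripts gives E (n x d). A truncated SVD, E = U S V^T, applied without
centering or scaling, yields orthonormal right singular vectors v_1..v_k —
directions in embedding space ordered by explained variance. ``emb_1`` of a
transcript is the scalar projection of its embedding onto one chosen column
of V (default: the second, which in practice can carry more label signal
than the dominant direction when the leading axis is stylistic rather than
topical). ``select_component`` offers the data-driven alternative: pick the
column whose projection has the largest |point-biserial correlation| with
the labels.

The default backend is a deterministic hashed bag-of-words embedding: token
counts hashed into buckets, mapped through a seeded random Gaussian
projection, and L2-normalized per row. A sentence-transformer backend can be
plugged in when that library is available; it satisfies the same contract.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DegenerateLabelsError, ShapeError

_HASH_BUCKETS = 2**18


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class EmbeddingMatrix:
    """n transcripts x d dims of real-valued embeddings, with aligned ids."""

    rows: np.ndarray
    ids: list[str]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2:
            raise ShapeError("embedding matrix must be 2-D")
        if self.rows.shape[0] != len(self.ids):
            raise ShapeError(
                f"{self.rows.shape[0]} rows but {len(self.ids)} ids"
            )
        if self.rows.shape[1] < 2:
            raise ShapeError("embedding dimension must be >= 2")
        if not np.all(np.isfinite(self.rows)):
            raise ShapeError("non-finite embedding entries")

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def d(self) -> int:
        return self.rows.shape[1]


@dataclass
class SvdProjector:
    """Fitted right singular vectors; maps an embedding to ``emb_1``.

    ``V`` is d x k with orthonormal columns v_1..v_k, singular values
    nonincreasing. The sign of each column is fixed so that its
    largest-|entry| coordinate is positive, resolving the inherent sign
    ambiguity of singular vectors. ``component_index`` (1-based) names the
    column used for ``emb_1``.
    """

    V: np.ndarray
    singular_values: np.ndarray
    component_index: int = 2
    sign_convention: str = "max-abs-positive"
    backend: str = "hashed"
    backend_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.V.ndim != 2 or self.V.shape[1] != self.singular_values.shape[0]:
            raise ShapeError("V columns must match singular value count")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ConfigError("singular values must be nonincreasing")
        if not (1 <= self.component_index <= self.k):
            raise ConfigError(
                f"component_index {self.component_index} outside 1..{self.k}"
            )
        gram = self.V.T @ self.V
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ConfigError("columns of V are not orthonormal to 1e-8")

    @property
    def d(self) -> int:
        return self.V.shape[0]

    @property
    def k(self) -> int:
        return self.V.shape[1]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "dims": self.d,
            "k": self.k,
            "component_index": self.component_index,
            "singular_values": self.singular_values.tolist(),
            "V": self.V.tolist(),
            "sign_convention": self.sign_convention,
            "backend": self.backend,
            "backend_config": self.backend_config,
            "config_hash": self.config_hash(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SvdProjector":
        obj = json.loads(text)
        return cls(
            V=np.array(obj["V"], dtype=float),
            singular_values=np.array(obj["singular_values"], dtype=float),
            component_index=obj["component_index"],
            sign_convention=obj["sign_convention"],
            backend=obj.get("backend", "hashed"),
            backend_config=obj.get("backend_config", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SvdProjector":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def config_hash(self) -> str:
        blob = json.dumps(
            {"backend": self.backend, "backend_config": self.backend_config},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# Hashed bag-of-words backend
# --------------------------------------------------------------------------


def _token_bucket(token: str) -> int:
    digest = hashlib.md5(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % _HASH_BUCKETS


def hashed_embedding(texts: Sequence[str], dim: int = 256, seed: int = 0) -> EmbeddingMatrix:
    """Deterministic bag-of-words embedding via token hashing + random projection.

    Token counts are hashed (MD5, stable across processes) into a large
    bucket space; each occupied bucket is mapped to a Gaussian vector in
    ``dim`` dimensions drawn from a counter-based RNG keyed on (seed,
    bucket), so the projection of a token never depends on which other
    tokens appear. Rows are L2-normalized; an all-zero row (empty text) is
    left as zeros and recorded in the warning list.
    """
    if dim < 2:
        raise ConfigError("embedding dim must be >= 2")
    rows = np.zeros((len(texts), dim), dtype=float)
    warnings: list[str] = []
    bucket_vectors: dict[int, np.ndarray] = {}
    for i, text in enumerate(texts):
        tokens = text.split()
        if not tokens:
            warnings.append(f"row {i}: empty text, zero embedding")
            continue
        counts: dict[int, int] = {}
        for tok in tokens:
            b = _token_bucket(tok)
            counts[b] = counts.get(b, 0) + 1
        vec = np.zeros(dim)
        for b, c in counts.items():
            bv = bucket_vectors.get(b)
            if bv is None:
                bv = np.random.default_rng([seed, b]).standard_normal(dim)
                bucket_vectors[b] = bv
            vec += c * bv
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec = vec / norm
        else:  # pragma: no cover - astronomically unlikely cancellation
            warnings.append(f"row {i}: zero-norm projection")
        rows[i] = vec
    return EmbeddingMatrix(rows=rows, ids=[str(i) for i in range(len(texts))], warnings=warnings)


def sentence_transformer_embedding(
    texts: Sequence[str],
    model_name: str = "all-MiniLM-L6-v2",
    normalize: bool = True,
) -> EmbeddingMatrix:  # pragma: no cover - optional backend, untested plumbing
    """Optional sentence-transformer backend (requires the library installed)."""
    try:
        from sentence_transformers import SentenceTransformer
    except ImportError as exc:
        raise ConfigError(
            "sentence-transformers is not installed; use the hashed backend"
        ) from exc
    model = SentenceTransformer(model_name)
    rows = np.asarray(model.encode(list(texts), normalize_embeddings=normalize))
    return EmbeddingMatrix(rows=rows, ids=[str(i) for i in range(len(texts))])


# --------------------------------------------------------------------------
# SVD fitting and projection
# --------------------------------------------------------------------------


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-|entry| coordinate positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            V[:, j] = -col
    return V


def fit_svd_projector(
    E_train: EmbeddingMatrix,
    k: int = 8,
    component_index: int = 2,
    backend: str = "hashed",
    backend_config: Optional[dict] = None,
) -> SvdProjector:
    """Top-k right singular vectors of the training embeddings (no centering)."""
    n, d = E_train.rows.shape
    if n < 2:
        raise ConfigError("need at least 2 training embeddings")
    if not (1 <= k <= min(n, d)):
        raise ConfigError(f"k={k} outside 1..min(n, d)={min(n, d)}")
    _U, s, Vt = np.linalg.svd(E_train.rows, full_matrices=False)
    V = _fix_signs(Vt[:k].T)
    return SvdProjector(
        V=V,
        singular_values=s[:k],
        component_index=min(component_index, k),
        backend=backend,
        backend_config=backend_config or {},
    )


def project_component(e: np.ndarray, projector: SvdProjector, j: Optional[int] = None) -> float:
    """Dot product of an embedding row with the j-th right singular vector."""
    e = np.asarray(e, dtype=float).ravel()
    if e.shape[0] != projector.d:
        raise ShapeError(f"embedding length {e.shape[0]} != projector dims {projector.d}")
    if j is None:
        j = projector.component_index
    if not (1 <= j <= projector.k):
        raise ConfigError(f"component {j} outside 1..{projector.k}")
    return float(e @ projector.V[:, j - 1])


def project_matrix(E: EmbeddingMatrix, projector: SvdProjector, j: Optional[int] = None) -> np.ndarray:
    """Vectorized :func:`project_component` over all rows."""
    if E.d != projector.d:
        raise ShapeError(f"embedding dims {E.d} != projector dims {projector.d}")
    if j is None:
        j = projector.component_index
    return E.rows @ projector.V[:, j - 1]


def point_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between a continuous variable and binary labels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def orient_to_labels(
    projector: SvdProjector, E_train: EmbeddingMatrix, labels: Sequence[int]
) -> SvdProjector:
    """Flip the selected component so its training-set label correlation is
    positive (higher projection = more label-1-like), resolving the sign
    ambiguity that the max-abs-positive convention fixes arbitrarily."""
    y = np.asarray(labels, dtype=int)
    j = projector.component_index
    corr = point_biserial(project_matrix(E_train, projector, j), y)
    V = projector.V.copy()
    if corr < 0:
        V[:, j - 1] = -V[:, j - 1]
    return SvdProjector(
        V=V,
        singular_values=projector.singular_values,
        component_index=j,
        sign_convention="label-oriented",
        backend=projector.backend,
        backend_config=projector.backend_config,
    )


def select_component(
    E_train: EmbeddingMatrix, labels: Sequence[int], k: Optional[int] = None,
    projector: Optional[SvdProjector] = None,
) -> int:
    """1-based index of the SVD component most correlated with the labels.

    Fits (or reuses) a projector, computes the point-biserial correlation of
    each component's training projections with the binary labels, and
    returns the argmax of |correlation|; ties break toward the smaller
    index.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise DegenerateLabelsError("select_component requires both classes")
    if projector is None:
        projector = fit_svd_projector(E_train, k=k or 8, component_index=1)
    best_j, best_corr = 1, -1.0
    for j in range(1, projector.k + 1):
        corr = abs(point_biserial(project_matrix(E_train, projector, j), y))
        if corr > best_corr + 1e-15:
            best_j, best_corr = j, corr
    return best_j
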