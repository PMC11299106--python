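"""k-mer word embeddings for DNA fragments.

DNA sequences are treated as sentences of overlapping k-mer "words".  A
skip-gram model with negative sampling learns a dense vector per k-mer from
unlabelled genome sequences; a fragment is then featurized as the arithmetic
mean of the vectors of its k-mers.

The trainer exploits the tiny DNA vocabulary (at most 4^k tokens): instead of
streaming (center, context) pairs, it accumulates the exact center-context
co-occurrence counts over the corpus and optimizes the negative-sampling
objective in full batch, with the negative term taken in expectation over the
unigram^0.75 noise distribution.  This is the same objective as pair-wise
stochastic training, is deterministic given the seed, and its cost does not
grow with corpus size.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingConfig",
    "EmbeddingModel",
    "FragmentFeature",
    "FeaturizationError",
    "tokenize",
    "train_embedding",
    "featurize",
    "featurize_many",
    "save_embedding",
    "load_embedding",
]

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class FeaturizationError(ValueError):
    """Raised when a sequence yields no usable k-mer token."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the k-mer skip-gram model.

    ``context_size`` is the total number of context words per center
    (half upstream, half downstream).  ``max_corpus_tokens`` caps the number
    of corpus tokens used to accumulate co-occurrence counts; sequences are
    consumed in order until the budget is exhausted.
    """

    k: int = 4
    dimension: int = 100
    context_size: int = 20
    epochs: int = 10
    negative_samples: int = 5
    seed: int = 0
    min_count: int = 1
    max_corpus_tokens: int | None = 500_000
    steps_per_epoch: int = 100
    learning_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.dimension < 1:
            raise ValueError(f"dimension must be >= 1, got {self.dimension}")
        if self.context_size < 2 or self.context_size % 2:
            raise ValueError(
                f"context_size must be even and >= 2, got {self.context_size}"
            )
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.negative_samples < 1:
            raise ValueError("negative_samples must be >= 1")

    @property
    def window(self) -> int:
        """One-sided context window (context_size / 2)."""
        return self.context_size // 2


@dataclass
class EmbeddingModel:
    """A trained k-mer -> vector map plus its training configuration."""

    config: EmbeddingConfig
    vocabulary: set[str]
    vectors: dict[str, np.ndarray]
    # dense (4^k, dim) lookup for fast batched featurization; rows for
    # out-of-vocabulary token ids are zero and masked via _present.
    _dense: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _present: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._dense is None:
            self._build_dense()

    def _build_dense(self) -> None:
        k, d = self.config.k, self.config.dimension
        self._dense = np.zeros((4**k, d), dtype=np.float64)
        self._present = np.zeros(4**k, dtype=bool)
        for tok, vec in self.vectors.items():
            idx = _token_to_id(tok)
            self._dense[idx] = vec
            self._present[idx] = True

    @property
    def k(self) -> int:
        return self.config.k

    @property
    def dimension(self) -> int:
        return self.config.dimension

    def checksum(self) -> str:
        """SHA-256 over (k, dimension, sorted token/vector pairs).

        Used by the classifier archive to refuse prediction with a
        mismatched embedding.
        """
        h = hashlib.sha256()
        h.update(f"{self.k} {self.dimension}".encode())
        for tok in sorted(self.vectors):
            h.update(tok.encode())
            h.update(np.asarray(self.vectors[tok], dtype=np.float64).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class FragmentFeature:
    """Mean k-mer word vector of one fragment."""

    fragment_id: str
    vector: np.ndarray


def _token_to_id(token: str) -> int:
    idx = 0
    for ch in token:
        idx = idx * 4 + int(_CODE[ord(ch)])
    return idx


def _id_to_token(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def _token_ids(sequence: str, k: int) -> np.ndarray:
    """Integer ids of all valid k-mer windows, in order; invalid dropped.

    A window is dropped if it contains any character outside {A,C,G,T}
    (case-insensitive).
    """
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={k}: no tokens"
        )
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    pw = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    ids = win[valid].astype(np.int64) @ pw
    return ids


def tokenize(sequence: str, k: int) -> list[str]:
    """Split a DNA sequence into its overlapping k-mer words.

    Returns the L-k+1 windows in order; windows containing a non-ACGT
    character (N or other IUPAC ambiguity codes) are dropped.  Raises
    ``ValueError`` if the sequence is shorter than k.
    """
    ids = _token_ids(sequence, k)
    return [_id_to_token(int(i), k) for i in ids]


def _cooccurrence(
    corpus: list[str], cfg: EmbeddingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Exact center-context co-occurrence counts over the corpus.

    Returns ``(counts, token_counts)`` where ``counts[i, j]`` is the number
    of (center i, context j) pairs within the one-sided window, summed over
    both directions, and ``token_counts[i]`` is the unigram count.  Windows
    never cross sequence boundaries.
    """
    V = 4**cfg.k
    counts = np.zeros(V * V, dtype=np.float64)
    token_counts = np.zeros(V, dtype=np.float64)
    budget = cfg.max_corpus_tokens
    used = 0
    for seq in corpus:
        if len(seq) < cfg.k:
            continue
        ids = _token_ids(seq, cfg.k)
        if ids.size == 0:
            continue
        if budget is not None:
            if used >= budget:
                break
            if used + ids.size > budget:
                ids = ids[: budget - used]
        used += ids.size
        token_counts += np.bincount(ids, minlength=V)
        for off in range(1, min(cfg.window, ids.size - 1) + 1):
            left, right = ids[:-off], ids[off:]
            # center=left with context to the right, and vice versa
            counts += np.bincount(left * V + right, minlength=V * V)
            counts += np.bincount(right * V + left, minlength=V * V)
    return counts.reshape(V, V), token_counts


def train_embedding(corpus: list[str], config: EmbeddingConfig | None = None) -> EmbeddingModel:
    """Train skip-gram k-mer vectors with negative sampling.

    The vocabulary is the set of k-mers observed at least ``min_count``
    times.  Optimization is full-batch over the exact co-occurrence counts:
    the maximized objective is

        sum_ij N_ij log s(w_i . c_j)
        + negative_samples * sum_i n_i sum_j P_n(j) log s(-w_i . c_j)

    with ``P_n`` the unigram^0.75 noise distribution and ``s`` the logistic
    function.  Deterministic given ``config.seed``.
    """
    cfg = config or EmbeddingConfig()
    if not corpus:
        raise ValueError("empty corpus: nothing to train on")
    if not any(len(s) >= cfg.k for s in corpus):
        raise ValueError(f"no corpus sequence of length >= k={cfg.k}")

    counts, token_counts = _cooccurrence(corpus, cfg)
    vocab_mask = token_counts >= max(1, cfg.min_count)
    vocab_ids = np.flatnonzero(vocab_mask)
    if vocab_ids.size == 0:
        raise ValueError("empty vocabulary after min_count filtering")

    N = counts[np.ix_(vocab_ids, vocab_ids)]
    total_pairs = N.sum()
    if total_pairs == 0:
        # degenerate: single-token sequences only; leave vectors at init
        total_pairs = 1.0

    uni = token_counts[vocab_ids]
    noise = uni**0.75
    noise /= noise.sum()
    center_w = N.sum(axis=1)  # per-center pair counts

    V, d = vocab_ids.size, cfg.dimension
    rng = np.random.default_rng(cfg.seed)
    W = rng.uniform(-0.5 / d, 0.5 / d, size=(V, d))
    C = np.zeros((V, d))

    # Adam on the normalized negative log-likelihood
    steps = cfg.epochs * cfg.steps_per_epoch
    lr, b1, b2, eps = cfg.learning_rate, 0.9, 0.999, 1e-8
    m = [np.zeros_like(W), np.zeros_like(C)]
    v = [np.zeros_like(W), np.zeros_like(C)]
    neg_weight = cfg.negative_samples * np.outer(center_w, noise)
    scale = 1.0 / total_pairs
    for t in range(1, steps + 1):
        S = 1.0 / (1.0 + np.exp(-(W @ C.T)))  # (V, V) sigmoid of all dots
        # d/d(dot): positive pairs want (1 - S), negatives want -S
        G = (N * (1.0 - S) - neg_weight * S) * scale
        grads = (G @ C, G.T @ W)
        for p, g, mi, vi in zip((W, C), grads, m, v):
            mi += (1 - b1) * (g - mi)
            vi += (1 - b2) * (g * g - vi)
            mhat = mi / (1 - b1**t)
            vhat = vi / (1 - b2**t)
            p += lr * mhat / (np.sqrt(vhat) + eps)  # ascent

    vectors = {
        _id_to_token(int(gid), cfg.k): W[row].copy()
        for row, gid in enumerate(vocab_ids)
    }
    vocab = set(vectors)
    return EmbeddingModel(config=cfg, vocabulary=vocab, vectors=vectors)


def featurize(sequence: str, model: EmbeddingModel, fragment_id: str = "") -> FragmentFeature:
    """Mean word vector of all in-vocabulary k-mers of a sequence.

    Out-of-vocabulary tokens are skipped.  Raises
    :class:`FeaturizationError` when no usable token remains.
    """
    try:
        ids = _token_ids(sequence, model.k)
    except ValueError as exc:
        raise FeaturizationError(str(exc)) from exc
    ids = ids[model._present[ids]]
    if ids.size == 0:
        raise FeaturizationError(
            f"fragment {fragment_id or '<anonymous>'}: no in-vocabulary k-mer"
        )
    return FragmentFeature(fragment_id, model._dense[ids].mean(axis=0))


def featurize_many(
    sequences: list[str], model: EmbeddingModel
) -> tuple[np.ndarray, np.ndarray]:
    """Batched featurization.

    Returns ``(X, ok)`` where ``X`` is (n, dimension) and ``ok`` is a boolean
    mask; rows with ``ok=False`` could not be featurized and contain zeros.
    """
    n = len(sequences)
    X = np.zeros((n, model.dimension))
    ok = np.zeros(n, dtype=bool)
    for i, seq in enumerate(sequences):
        try:
            X[i] = featurize(seq, model).vector
            ok[i] = True
        except FeaturizationError:
            pass
    return X, ok


def save_embedding(model: EmbeddingModel, path) -> None:
    """Write the plain-text embedding format: header ``k dimension``, then
    one ``token v1 v2 ...`` line per k-mer."""
    with open(path, "w") as fh:
        fh.write(f"{model.k} {model.dimension}\n")
        for tok in sorted(model.vectors):
            vals = " ".join(repr(float(x)) for x in model.vectors[tok])
            fh.write(f"{tok} {vals}\n")


def load_embedding(path) -> EmbeddingModel:
    """Load an embedding written by :func:`save_embedding`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed embedding header")
        k, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            tok, vals = parts[0], parts[1:]
            if len(tok) != k or any(c not in _BASES for c in tok):
                raise ValueError(f"{path}:{lineno}: bad token {tok!r}")
            if len(vals) != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} values, got {len(vals)}"
                )
            vectors[tok] = np.array([float(x) for x in vals])
    cfg = EmbeddingConfig(k=k, dimension=dim)
    return EmbeddingModel(config=cfg, vocabulary=set(vectors), vectors=vectors)
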