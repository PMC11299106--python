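"""Length-binned random-forest ensemble for MOB typing of DNA fragments.

Four forests, one per training length range, are trained on mean-word-vector
features.  At prediction time a fragment up to 1600 bp is scored by the
forest of its length bin (fragments under 100 bp use the 100-400 bp model);
longer fragments are segmented greedily left-to-right into 1600 bp pieces
plus a remainder, each piece is scored by its bin's model, and the piece
score vectors are combined as a length-weighted mean.  Bins of fragments are
scored as the length-weighted mean of their members' score vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .benchmark_sim import LabeledFragment
from .constants import CLASS_ORDER, LENGTH_BINS, SEGMENT_LENGTH, UNCLASSIFIED
from .embedding import EmbeddingModel, FeaturizationError, featurize, featurize_many

__all__ = [
    "MobClassScores",
    "EnsembleModel",
    "BinPrediction",
    "assign_length_bin",
    "segment_fragment",
    "train_ensemble",
    "predict_fragment",
    "predict_fragments",
    "predict_bin",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class MobClassScores:
    """An 11-way score vector over the fixed class order, summing to 1."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(CLASS_ORDER),):
            raise ValueError(f"expected {len(CLASS_ORDER)} scores, got {s.shape}")
        if (s < -1e-12).any() or abs(s.sum() - 1.0) > 1e-9:
            raise ValueError("scores must be nonnegative and sum to 1")
        object.__setattr__(self, "scores", s)

    @property
    def predicted_class(self) -> str:
        # argmax returns the first maximum, i.e. ties break to the earliest
        # class in the fixed order
        return CLASS_ORDER[int(np.argmax(self.scores))]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CLASS_ORDER, self.scores.tolist()))


@dataclass(frozen=True)
class BinPrediction:
    """Length-weighted aggregate prediction for one metagenomic bin."""

    bin_id: str
    scores: MobClassScores
    member_count: int
    total_length: int


@dataclass
class EnsembleModel:
    """Four length-specific forests plus the embedding they were trained with."""

    per_bin_models: dict[str, RandomForestClassifier]
    embedding: EmbeddingModel
    class_order: tuple[str, ...]
    seed: int
    embedding_checksum: str = ""
    version: int = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        if set(self.per_bin_models) != set(LENGTH_BINS):
            raise ValueError(
                f"expected models for bins {sorted(LENGTH_BINS)}, "
                f"got {sorted(self.per_bin_models)}"
            )
        if tuple(self.class_order) != CLASS_ORDER:
            raise ValueError("class_order must match the fixed class order")
        if not self.embedding_checksum:
            self.embedding_checksum = self.embedding.checksum()


def assign_length_bin(length: int) -> str:
    """Length bin serving a fragment of the given length.

    Fragments shorter than 100 bp use the 100-400 bp model (B1); lengths
    above 1600 bp must be segmented first and are a contract violation here.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if length > SEGMENT_LENGTH:
        raise ValueError(
            f"length {length} > {SEGMENT_LENGTH}: segment the fragment first"
        )
    for name, (lo, hi) in LENGTH_BINS.items():
        if length <= hi:
            return name
    raise AssertionError("unreachable")


def segment_fragment(sequence: str) -> list[str]:
    """Greedy left-to-right segmentation into 1600 bp pieces plus remainder.

    Sequences of 1600 bp or less pass through as a single segment.  The
    concatenation of the returned pieces always equals the input.
    """
    L = len(sequence)
    if L <= SEGMENT_LENGTH:
        return [sequence]
    pieces = [
        sequence[i : i + SEGMENT_LENGTH] for i in range(0, L, SEGMENT_LENGTH)
    ]
    return pieces


def train_ensemble(
    fragments: list[LabeledFragment],
    embedding: EmbeddingModel,
    n_trees: int = 500,
    seed: int = 0,
) -> EnsembleModel:
    """Train one forest per length bin on featurized training fragments.

    Fragments are routed to bins by their length.  Each bin must contain at
    least two classes.  Deterministic given the seed (single-threaded).
    """
    by_bin: dict[str, list[LabeledFragment]] = {name: [] for name in LENGTH_BINS}
    for fr in fragments:
        by_bin[assign_length_bin(len(fr.sequence))].append(fr)
    models: dict[str, RandomForestClassifier] = {}
    for bi, (name, members) in enumerate(by_bin.items()):
        if not members:
            raise ValueError(f"length bin {name}: no training fragments")
        X, ok = featurize_many([fr.sequence for fr in members], embedding)
        y = np.array([CLASS_ORDER.index(fr.true_class) for fr in members])
        X, y = X[ok], y[ok]
        if np.unique(y).size < 2:
            raise ValueError(
                f"length bin {name}: needs fragments from >= 2 classes"
            )
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + bi, n_jobs=1
        )
        rf.fit(X, y)
        models[name] = rf
    return EnsembleModel(
        per_bin_models=models,
        embedding=embedding,
        class_order=CLASS_ORDER,
        seed=seed,
    )


def _proba_full(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Forest class probabilities expanded to the full fixed class order and
    defensively renormalized."""
    p = rf.predict_proba(X)
    full = np.zeros((X.shape[0], len(CLASS_ORDER)))
    full[:, rf.classes_.astype(int)] = p
    full = np.clip(full, 0.0, None)
    full /= full.sum(axis=1, keepdims=True)
    return full


def predict_fragment(sequence: str, model: EnsembleModel) -> MobClassScores:
    """Score one fragment of any length.

    Up to 1600 bp the score is the raw per-bin forest output; beyond that
    the fragment is segmented and the segment score vectors are combined as
    a length-weighted mean (weights = segment lengths / total length).
    Raises :class:`FeaturizationError` if no segment is featurizable.
    """
    segments = segment_fragment(sequence)
    vecs, lens = [], []
    for seg in segments:
        try:
            vecs.append(featurize(seg, model.embedding).vector)
            lens.append(len(seg))
        except FeaturizationError:
            continue
    if not vecs:
        raise FeaturizationError("fragment has no featurizable segment")
    per_seg = np.vstack(
        [
            _proba_full(
                model.per_bin_models[assign_length_bin(L)], v[None, :]
            )[0]
            for v, L in zip(vecs, lens)
        ]
    )
    w = np.array(lens, dtype=float)
    combined = (w[:, None] * per_seg).sum(axis=0) / w.sum()
    return MobClassScores(combined / combined.sum())


def predict_fragments(
    sequences: list[str], model: EnsembleModel
) -> list[MobClassScores | None]:
    """Batched fragment scoring; None marks unclassifiable fragments.

    Short fragments (<= 1600 bp) are grouped per bin and scored in a single
    forest call per bin, which is much faster than per-fragment calls.
    """
    n = len(sequences)
    out: list[MobClassScores | None] = [None] * n
    short_idx: dict[str, list[int]] = {name: [] for name in LENGTH_BINS}
    short_vec: dict[str, list[np.ndarray]] = {name: [] for name in LENGTH_BINS}
    for i, seq in enumerate(sequences):
        if len(seq) > SEGMENT_LENGTH:
            try:
                out[i] = predict_fragment(seq, model)
            except FeaturizationError:
                out[i] = None
            continue
        try:
            vec = featurize(seq, model.embedding).vector
        except FeaturizationError:
            continue
        bin_name = assign_length_bin(len(seq))
        short_idx[bin_name].append(i)
        short_vec[bin_name].append(vec)
    for name, idxs in short_idx.items():
        if not idxs:
            continue
        P = _proba_full(model.per_bin_models[name], np.vstack(short_vec[name]))
        for row, i in enumerate(idxs):
            out[i] = MobClassScores(P[row] / P[row].sum())
    return out


def predict_bin(
    fragments: list[tuple[str, str]],
    bin_id: str,
    model: EnsembleModel,
) -> BinPrediction | None:
    """Length-weighted aggregate score for a bin of (fragment_id, sequence).

    Bin score = sum_f len(f) * scores(f) / sum_f len(f) over classifiable
    members.  Returns None when the bin is empty or no member is
    classifiable.
    """
    if not fragments:
        return None
    seqs = [s for _, s in fragments]
    scores = predict_fragments(seqs, model)
    num = np.zeros(len(CLASS_ORDER))
    total = 0
    used = 0
    for (fid, seq), sc in zip(fragments, scores):
        if sc is None:
            continue
        num += len(seq) * sc.scores
        total += len(seq)
        used += 1
    if used == 0:
        return None
    combined = num / num.sum()
    return BinPrediction(
        bin_id=bin_id,
        scores=MobClassScores(combined),
        member_count=used,
        total_length=total,
    )


def save_model(model: EnsembleModel, path) -> None:
    """Persist the ensemble as a versioned archive (forests, embedding,
    class order, embedding checksum, seed)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "class_order": list(model.class_order),
        "seed": model.seed,
        "embedding_checksum": model.embedding_checksum,
        "embedding_config": model.embedding.config,
        "embedding_vectors": model.embedding.vectors,
        "per_bin_models": model.per_bin_models,
    }
    joblib.dump(payload, path)


def load_model(path) -> EnsembleModel:
    """Load a persisted ensemble; refuses mismatched versions or an
    embedding whose checksum no longer matches its vectors."""
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {version!r}"
        )
    emb = EmbeddingModel(
        config=payload["embedding_config"],
        vocabulary=set(payload["embedding_vectors"]),
        vectors=payload["embedding_vectors"],
    )
    if emb.checksum() != payload["embedding_checksum"]:
        raise ValueError(f"{path}: embedding checksum mismatch; refusing to predict")
    return EnsembleModel(
        per_bin_models=payload["per_bin_models"],
        embedding=emb,
        class_order=tuple(payload["class_order"]),
        seed=payload["seed"],
        embedding_checksum=payload["embedding_checksum"],
    )
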