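"""Synthetic class-labeled plasmid benchmark.

Generates class-distinct plasmid genomes with a first-order Markov chain over
{A,C,G,T}, splits them 70/30 at genome level, and samples fragments for the
four training length bins (100-400, 401-800, 801-1200, 1201-1600 bp) and the
four test groups (A: 801-1200, B: 1201-1600, C: 3000-4000, D: 5000-10000 bp).

Each of the 11 classes gets a GC target taken from the observed per-class GC
of real plasmid genomes (spread 0.27-0.57) plus a class-specific dinucleotide
tilt, so classes differ both in GC and in higher-order composition - the
signal the k-mer embedding and forest are meant to pick up.  The transition
matrix is calibrated so its stationary GC matches the target even under the
tilt.  Genomes are treated as linear for fragment sampling (no wrap across
the origin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CLASS_ORDER, LENGTH_BINS, TEST_GROUPS

__all__ = [
    "SyntheticClassProfile",
    "LabeledFragment",
    "default_profiles",
    "generate_class_genomes",
    "split_genomes",
    "sample_fragments",
    "generate_benchmark",
    "DEFAULT_GC",
    "DEFAULT_MEAN_LENGTH",
]

#: Per-class GC targets: observed GC fractions of real plasmid genomes by
#: MOB class (range 0.27-0.57).
DEFAULT_GC: dict[str, float] = {
    "MOBB": 0.5127,
    "MOBC": 0.4714,
    "MOBF": 0.5207,
    "MOBH": 0.4837,
    "MOBL": 0.3457,
    "MOBM": 0.2712,
    "MOBP": 0.4970,
    "MOBQ": 0.5677,
    "MOBT": 0.3692,
    "MOBV": 0.3775,
    "non-MOB": 0.4984,
}

#: Desk-scale per-class mean genome lengths (bp): the observed per-class
#: average plasmid lengths scaled down 10x and clipped to [3000, 12000] so
#: classes keep their relative length ordering while generation stays cheap.
_REAL_MEAN_LENGTH = {
    "MOBB": 10_921.77,
    "MOBC": 19_965.28,
    "MOBF": 103_802.80,
    "MOBH": 151_108.10,
    "MOBL": 51_430.63,
    "MOBM": 2_684.14,
    "MOBP": 32_237.88,
    "MOBQ": 89_357.64,
    "MOBT": 11_643.24,
    "MOBV": 6_595.43,
    "non-MOB": 37_581.85,
}
DEFAULT_MEAN_LENGTH: dict[str, int] = {
    c: int(np.clip(round(v / 10), 3000, 12000)) for c, v in _REAL_MEAN_LENGTH.items()
}

#: Strength of the class-specific dinucleotide tilt (log-scale multiplier on
#: transition weights).  0 means composition differs by GC only.
DEFAULT_BIAS_STRENGTH = 0.3

_BASES = "ACGT"
_GC_IDX = np.array([False, True, True, False])  # A C G T


@dataclass(frozen=True)
class SyntheticClassProfile:
    """Generation parameters for one MOB class."""

    class_label: str
    gc_content: float
    dinucleotide_bias: np.ndarray  # (4, 4) nonnegative weights
    mean_genome_length: int
    n_genomes: int
    seed: int
    length_cv: float = 0.15  # coefficient of variation of genome length

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError(f"gc_content must be in (0, 1), got {self.gc_content}")
        if self.mean_genome_length < 2000:
            raise ValueError("mean_genome_length must be >= 2000")
        b = np.asarray(self.dinucleotide_bias, dtype=float)
        if b.shape != (4, 4) or (b < 0).any() or not np.isfinite(b).all():
            raise ValueError("dinucleotide_bias must be a (4,4) nonnegative array")


@dataclass(frozen=True)
class LabeledFragment:
    """One benchmark fragment with its truth metadata."""

    fragment_id: str
    sequence: str
    true_class: str
    source_genome: str
    split: str  # "train" | "test"
    group: str  # length-bin name (B1..B4) or test-group name (A..D)


def default_profiles(
    n_genomes: int = 20,
    seed: int = 0,
    bias_strength: float = DEFAULT_BIAS_STRENGTH,
    mean_lengths: dict[str, int] | None = None,
) -> list[SyntheticClassProfile]:
    """The 11 default class profiles.

    Each class receives a deterministic dinucleotide tilt
    ``exp(bias_strength * U)`` with ``U ~ Uniform(-1, 1)^(4x4)`` drawn from a
    class-indexed stream, so profiles are stable across calls regardless of
    the top-level seed.
    """
    lengths = mean_lengths or DEFAULT_MEAN_LENGTH
    profiles = []
    for ci, cls in enumerate(CLASS_ORDER):
        tilt_rng = np.random.default_rng(977 + ci)
        bias = np.exp(bias_strength * tilt_rng.uniform(-1.0, 1.0, size=(4, 4)))
        profiles.append(
            SyntheticClassProfile(
                class_label=cls,
                gc_content=DEFAULT_GC[cls],
                dinucleotide_bias=bias,
                mean_genome_length=lengths[cls],
                n_genomes=n_genomes,
                seed=seed * 1009 + ci,
            )
        )
    return profiles


def _transition_matrix(gc: float, bias: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Row-stochastic transition matrix whose stationary GC equals ``gc``.

    Starts from base composition [(1-gc)/2, gc/2, gc/2, (1-gc)/2] modulated
    by the dinucleotide bias, then rescales the G/C columns by fixed-point
    iteration until the stationary distribution hits the GC target.
    """
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    scale = np.ones(4)
    T = None
    for _ in range(200):
        T = bias * (base * scale)[None, :]
        T /= T.sum(axis=1, keepdims=True)
        pi = _stationary(T)
        cur_gc = pi[_GC_IDX].sum()
        if abs(cur_gc - gc) < tol:
            break
        ratio = (gc / cur_gc) * ((1 - cur_gc) / (1 - gc))
        scale[_GC_IDX] *= ratio
    return T


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _markov_sequence(T: np.ndarray, length: int, rng: np.random.Generator) -> str:
    pi = _stationary(T)
    cum = np.cumsum(T, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    state = int(np.searchsorted(np.cumsum(pi), u[0]))
    state = min(state, 3)
    out[0] = state
    row = cum[state]
    for i in range(1, length):
        state = int(np.searchsorted(row, u[i]))
        state = min(state, 3)
        out[i] = state
        row = cum[state]
    return "".join(_BASES[b] for b in out)


def generate_class_genomes(
    profile: SyntheticClassProfile,
) -> list[tuple[str, str, str]]:
    """Generate ``n_genomes`` Markov genomes for one class.

    Returns (genome_id, sequence, class_label) triples; deterministic for a
    given profile (seed included).
    """
    rng = np.random.default_rng(profile.seed)
    T = _transition_matrix(profile.gc_content, np.asarray(profile.dinucleotide_bias, float))
    out = []
    for i in range(profile.n_genomes):
        length = int(
            max(
                2000,
                round(
                    rng.normal(
                        profile.mean_genome_length,
                        profile.length_cv * profile.mean_genome_length,
                    )
                ),
            )
        )
        seq = _markov_sequence(T, length, rng)
        out.append((f"{profile.class_label}_g{i:03d}", seq, profile.class_label))
    return out


def split_genomes(
    genomes: list[tuple[str, str, str]],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Per-class genome-level 70/30 split.

    Every class must have at least 2 genomes; |train| = round(f * n) per
    class, clamped so neither side is empty.  No genome appears on both
    sides.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[tuple[str, str, str]]] = {}
    for g in genomes:
        by_class.setdefault(g[2], []).append(g)
    train, test = [], []
    for cls in sorted(by_class):
        members = sorted(by_class[cls], key=lambda g: g[0])
        if len(members) < 2:
            raise ValueError(
                f"class {cls}: need >= 2 genomes to split, got {len(members)}"
            )
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return train, test


def sample_fragments(
    genomes: list[tuple[str, str, str]],
    length_range: tuple[int, int],
    n_per_class: int,
    seed: int = 0,
    split: str = "train",
    group: str = "",
) -> list[LabeledFragment]:
    """Randomly extract ``n_per_class`` fragments per class in a length range.

    Genomes are sampled uniformly with replacement; fragment length is
    uniform over the range (capped by genome length) and the start position
    uniform over valid positions.  Classes with no genome reaching the range
    minimum get a warning and fewer (possibly zero) fragments.
    """
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError(f"bad length range {length_range}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[tuple[str, str, str]]] = {}
    for g in genomes:
        by_class.setdefault(g[2], []).append(g)
    frags: list[LabeledFragment] = []
    tag = group or f"{lo}-{hi}"
    for cls in sorted(by_class):
        members = sorted(by_class[cls], key=lambda g: g[0])
        usable = [g for g in members if len(g[1]) >= lo]
        if not usable:
            warnings.warn(
                f"class {cls}: no genome of length >= {lo}; skipping range {lo}-{hi}"
            )
            continue
        for j in range(n_per_class):
            gid, seq, _ = usable[rng.integers(len(usable))]
            L = int(rng.integers(lo, min(hi, len(seq)) + 1))
            start = int(rng.integers(0, len(seq) - L + 1))
            frags.append(
                LabeledFragment(
                    fragment_id=f"{cls}_{tag}_{split}_f{j:05d}",
                    sequence=seq[start : start + L],
                    true_class=cls,
                    source_genome=gid,
                    split=split,
                    group=tag,
                )
            )
    return frags


def generate_benchmark(
    n_genomes: int = 20,
    n_train_per_class_per_bin: int = 2000,
    n_test_per_class_per_group: int = 500,
    seed: int = 0,
    profiles: list[SyntheticClassProfile] | None = None,
    train_fraction: float = 0.7,
    test_groups: dict[str, tuple[int, int]] | None = None,
) -> dict:
    """Full benchmark: genomes, 70/30 split, per-bin training fragments and
    per-group test fragments.

    Returns a dict with keys ``genomes``, ``train_genomes``,
    ``test_genomes``, ``train_fragments`` (bin name -> list) and
    ``test_fragments`` (group name -> list).
    """
    profs = profiles or default_profiles(n_genomes=n_genomes, seed=seed)
    genomes: list[tuple[str, str, str]] = []
    for p in profs:
        genomes.extend(generate_class_genomes(p))
    train_g, test_g = split_genomes(genomes, train_fraction, seed=seed + 1)
    train_fragments = {
        name: sample_fragments(
            train_g, rng_range, n_train_per_class_per_bin,
            seed=seed + 100 + i, split="train", group=name,
        )
        for i, (name, rng_range) in enumerate(LENGTH_BINS.items())
    }
    groups = test_groups or TEST_GROUPS
    test_fragments = {
        name: sample_fragments(
            test_g, rng_range, n_test_per_class_per_group,
            seed=seed + 200 + i, split="test", group=name,
        )
        for i, (name, rng_range) in enumerate(groups.items())
    }
    return {
        "genomes": genomes,
        "train_genomes": train_g,
        "test_genomes": test_g,
        "train_fragments": train_fragments,
        "test_fragments": test_fragments,
    }
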