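"""MOB labeling of complete plasmid genomes from relaxase alignment hits.

Complete plasmid genomes are assigned to one of ten relaxase (MOB) families
or to non-MOB by scoring protein-alignment hits against a reference relaxase
set.  The homology confidence score is

    mob_score = sqrt(0.01 * qcov_max * (1 - 1 / log10(bitscore_max)))

where qcov_max and bitscore_max belong to the best-scoring hit.  A genome is
"sure" in a class when its best hit there has mob_score > 0.5 and
e-value <= 1e-10; genomes with no hit, or whose hits all have e-value
> 0.01, are non-MOB.  Genomes sure in more than one class are ambiguous and
excluded from benchmark construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .constants import MOB_CLASSES, NON_MOB

__all__ = [
    "AlignmentHit",
    "GenomeMobLabel",
    "HomologFilterConfig",
    "mob_score",
    "filter_homolog_hits",
    "best_hits_per_class",
    "classify_genome",
    "label_genomes",
    "build_benchmark_labels",
    "read_hit_table",
    "read_class_map",
]

#: e-value above which a genome is called non-MOB even if hits exist.
NON_MOB_EVALUE = 0.01
#: thresholds defining the "sure" confidence level.
SURE_MOB_SCORE = 0.5
SURE_EVALUE = 1e-10

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qcovs",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One protein-alignment result row (query = genome CDS, subject =
    reference relaxase of a known MOB class)."""

    query_id: str
    subject_id: str
    subject_mob_class: str
    percent_identity: float
    query_coverage: float
    bitscore: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.query_coverage <= 100:
            raise ValueError(
                f"query_coverage must be in [0, 100], got {self.query_coverage}"
            )
        if self.bitscore < 0:
            raise ValueError(f"bitscore must be >= 0, got {self.bitscore}")
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if self.subject_mob_class not in MOB_CLASSES:
            raise ValueError(f"unknown MOB class {self.subject_mob_class!r}")


@dataclass(frozen=True)
class HomologFilterConfig:
    """Thresholds for accepting reference-relaxase homologs."""

    e_value_max: float = 1e-10
    query_coverage_min: float = 70.0
    identity_min: float = 70.0

    def __post_init__(self) -> None:
        if self.e_value_max < 0 or self.query_coverage_min < 0 or self.identity_min < 0:
            raise ValueError("filter thresholds must be nonnegative")


@dataclass(frozen=True)
class GenomeMobLabel:
    """MOB assignment of one complete plasmid genome."""

    genome_id: str
    assigned_class: str
    confidence: str  # "sure" | "possible" | "non-MOB"
    mob_score: float | None = None
    best_hit: AlignmentHit | None = None


def mob_score(qcov_max: float, bitscore_max: float) -> float:
    """Relaxase homology confidence score in [0, 1].

    ``sqrt(0.01 * qcov_max * (1 - 1/log10(bitscore_max)))``.  For
    bitscore_max <= 10 the bracket is <= 0 and the score is defined as 0
    (such hits can never reach the 0.5 acceptance threshold).
    """
    if qcov_max < 0 or bitscore_max < 0:
        raise ValueError(
            f"qcov_max and bitscore_max must be nonnegative, "
            f"got {qcov_max}, {bitscore_max}"
        )
    if bitscore_max <= 10:
        return 0.0
    val = 0.01 * qcov_max * (1.0 - 1.0 / math.log10(bitscore_max))
    return math.sqrt(val)


def filter_homolog_hits(
    hits: list[AlignmentHit], config: HomologFilterConfig | None = None
) -> list[AlignmentHit]:
    """Keep hits passing the e-value, query-coverage and identity thresholds."""
    cfg = config or HomologFilterConfig()
    return [
        h
        for h in hits
        if h.e_value <= cfg.e_value_max
        and h.query_coverage >= cfg.query_coverage_min
        and h.percent_identity >= cfg.identity_min
    ]


def best_hits_per_class(hits: list[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Per MOB class, the hit with maximum bitscore.

    Ties are broken by minimum e-value, then lexicographic subject_id, so
    the result is independent of input order.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.subject_mob_class)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.subject_mob_class] = h
    return best


def _hit_rank(h: AlignmentHit) -> tuple[float, float, str]:
    return (-h.bitscore, h.e_value, h.subject_id)


def classify_genome(
    genome_id: str, best_hits: dict[str, AlignmentHit]
) -> GenomeMobLabel:
    """Assign a MOB class (or non-MOB) to one genome from its per-class best hits.

    Non-MOB when there is no hit or every hit has e-value > 0.01; otherwise
    the class whose best hit maximizes mob_score wins.  Confidence is "sure"
    iff that hit has mob_score > 0.5 and e-value <= 1e-10, else "possible".
    """
    if not genome_id:
        raise ValueError("empty genome_id")
    usable = {c: h for c, h in best_hits.items() if h.e_value <= NON_MOB_EVALUE}
    if not usable:
        return GenomeMobLabel(genome_id, NON_MOB, "non-MOB")
    scored = {c: mob_score(h.query_coverage, h.bitscore) for c, h in usable.items()}
    # deterministic across dict orderings: max score, then class name
    cls = max(scored, key=lambda c: (scored[c], c))
    hit = usable[cls]
    score = scored[cls]
    sure = score > SURE_MOB_SCORE and hit.e_value <= SURE_EVALUE
    return GenomeMobLabel(
        genome_id, cls, "sure" if sure else "possible", score, hit
    )


def sure_classes(best_hits: dict[str, AlignmentHit]) -> set[str]:
    """Classes in which a genome's best hit individually qualifies as sure."""
    return {
        c
        for c, h in best_hits.items()
        if mob_score(h.query_coverage, h.bitscore) > SURE_MOB_SCORE
        and h.e_value <= SURE_EVALUE
    }


def label_genomes(
    hits_by_genome: dict[str, list[AlignmentHit]],
    genome_ids: list[str] | None = None,
) -> tuple[list[GenomeMobLabel], dict[str, set[str]]]:
    """Label every genome and record its set of sure classes.

    ``genome_ids`` may list genomes with no hits at all (non-MOB); defaults
    to the keys of ``hits_by_genome``.
    """
    ids = list(genome_ids) if genome_ids is not None else sorted(hits_by_genome)
    labels: list[GenomeMobLabel] = []
    multi: dict[str, set[str]] = {}
    for gid in ids:
        best = best_hits_per_class(hits_by_genome.get(gid, []))
        labels.append(classify_genome(gid, best))
        multi[gid] = sure_classes(best)
    return labels, multi


def build_benchmark_labels(
    labels: list[GenomeMobLabel], sure_multiclass: dict[str, set[str]]
) -> list[GenomeMobLabel]:
    """Unambiguous benchmark set: non-MOB genomes plus genomes sure in
    exactly one class.  "possible" and multi-class-sure genomes are dropped."""
    out = []
    for lab in labels:
        if lab.confidence == "non-MOB":
            out.append(lab)
        elif (
            lab.confidence == "sure"
            and len(sure_multiclass.get(lab.genome_id, set())) == 1
        ):
            out.append(lab)
    return out


def read_class_map(path) -> dict[str, str]:
    """Two-column TSV mapping reference subject_id -> MOB class."""
    df = pd.read_csv(path, sep="\t", header=None, names=["subject_id", "mob_class"],
                     dtype=str, comment="#")
    bad = ~df["mob_class"].isin(MOB_CLASSES)
    if bad.any():
        raise ValueError(
            f"{path}: unknown MOB class(es) {sorted(df.loc[bad, 'mob_class'].unique())}"
        )
    return dict(zip(df["subject_id"], df["mob_class"]))


def read_hit_table(path, class_map: dict[str, str]) -> dict[str, list[AlignmentHit]]:
    """Parse a 13-column tabular alignment file (standard 12 columns plus
    qcovs) into hits grouped by query genome.

    Subjects missing from ``class_map`` raise; malformed rows raise with
    their line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed hit table: {exc}") from exc
    hits: dict[str, list[AlignmentHit]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        subj = str(row.subject_id)
        if subj not in class_map:
            raise ValueError(f"{path}:{lineno}: subject {subj!r} not in class map")
        try:
            hit = AlignmentHit(
                query_id=str(row.query_id),
                subject_id=subj,
                subject_mob_class=class_map[subj],
                percent_identity=float(row.pident),
                query_coverage=float(row.qcovs),
                bitscore=float(row.bitscore),
                e_value=float(row.evalue),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        hits.setdefault(hit.query_id, []).append(hit)
    return hits
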