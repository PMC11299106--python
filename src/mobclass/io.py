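"""File formats and run plumbing: FASTA, score tables, bin metatables,
manifests, logging and atomic writes.

All tabular outputs are TSV.  Output files are written to a temporary file
in the destination directory and atomically renamed, so a failed run never
leaves a partial file behind.  Gzip-compressed FASTA is accepted
transparently (by .gz suffix).
"""

from __future__ import annotations

import contextlib
import gzip
import hashlib
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, is_dataclass

import pandas as pd

from .classifier import MobClassScores
from .constants import CLASS_ORDER, UNCLASSIFIED

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bin_metatable",
    "write_fragment_scores",
    "write_bin_scores",
    "read_fragment_scores",
    "write_manifest",
    "read_manifest",
    "atomic_write",
    "get_logger",
    "log_stage",
    "config_hash",
]

logger = logging.getLogger("mobclass")


def get_logger() -> logging.Logger:
    return logger


def config_hash(config) -> str:
    """Short stable hash of a configuration object, for log provenance."""
    if is_dataclass(config) and not isinstance(config, type):
        payload = repr(sorted(asdict(config).items()))
    else:
        payload = repr(sorted(dict(config).items()))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def log_stage(stage: str, **fields) -> None:
    """One structured log line per pipeline stage."""
    kv = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s", stage, kv)


@contextlib.contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, rename on success."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file.

    Record ids are the first whitespace-delimited header token; sequences
    are uppercased.  Malformed files raise with a line number; duplicate
    ids and empty records are rejected.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    rec_id: str | None = None
    rec_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if rec_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec_id!r} (line {rec_line}) has an empty sequence")
        records.append((rec_id, seq))

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                rec_id = header.split()[0]
                rec_line = lineno
                if rec_id in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate record id {rec_id!r}")
                seen.add(rec_id)
                chunks = []
            else:
                if rec_id is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
        _flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with atomic_write(path) as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bin_metatable(path, fasta_ids: set[str] | None = None) -> dict[str, str]:
    """Two-column TSV mapping fragment_id -> bin_id.

    A header row is auto-detected (first row whose first field looks like a
    column name, i.e. matches 'fragment' or contains no data row pattern and
    is repeated nowhere as an id).  Duplicate fragment ids and fragments
    missing from the companion FASTA are errors.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, got {df.shape[1]}")
    if df.empty:
        raise ValueError(f"{path}: empty metatable")
    first = str(df.iloc[0, 0]).lower()
    if first in {"fragment", "fragment_id", "contig", "contig_id", "id"} or (
        fasta_ids is not None and str(df.iloc[0, 0]) not in fasta_ids and len(df) > 1
        and str(df.iloc[1, 0]) in fasta_ids
    ):
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    frag_ids = df.iloc[:, 0].tolist()
    dup = pd.Series(frag_ids).duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate fragment id(s) {sorted(set(pd.Series(frag_ids)[dup]))}"
        )
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if fasta_ids is not None:
        missing = [f for f in mapping if f not in fasta_ids]
        if missing:
            raise ValueError(
                f"{path}: fragment(s) absent from FASTA: {missing[:10]}"
            )
    return mapping


_SCORE_HEADER = ["fragment_id", "predicted_class", *CLASS_ORDER]


def write_fragment_scores(
    records: list[tuple[str, MobClassScores | None]], path
) -> None:
    """13-column TSV: id, predicted MOB type, then the 11 class scores
    (4 decimal places).  Unclassifiable fragments get the 'unclassified'
    sentinel and blank scores."""
    with atomic_write(path) as fh:
        fh.write("\t".join(_SCORE_HEADER) + "\n")
        for rid, sc in records:
            if sc is None:
                fh.write("\t".join([rid, UNCLASSIFIED] + [""] * len(CLASS_ORDER)) + "\n")
            else:
                vals = [f"{x:.4f}" for x in sc.scores]
                fh.write("\t".join([rid, sc.predicted_class, *vals]) + "\n")


def write_bin_scores(records, path) -> None:
    """Bin-level output: bin id, predicted class, 11 scores."""
    header = ["bin_id", "predicted_class", *CLASS_ORDER]
    with atomic_write(path) as fh:
        fh.write("\t".join(header) + "\n")
        for bin_id, pred in records:
            if pred is None:
                fh.write("\t".join([bin_id, UNCLASSIFIED] + [""] * len(CLASS_ORDER)) + "\n")
            else:
                vals = [f"{x:.4f}" for x in pred.scores.scores]
                fh.write("\t".join([bin_id, pred.scores.predicted_class, *vals]) + "\n")


def read_fragment_scores(path) -> pd.DataFrame:
    """Read a fragment (or bin) score table back into a DataFrame."""
    return pd.read_csv(path, sep="\t")


def write_manifest(fragments, path) -> None:
    """Truth manifest for benchmark fragments: one row per fragment."""
    with atomic_write(path) as fh:
        fh.write("fragment_id\ttrue_class\tsource_genome\tsplit\tgroup\tlength\n")
        for fr in fragments:
            fh.write(
                f"{fr.fragment_id}\t{fr.true_class}\t{fr.source_genome}"
                f"\t{fr.split}\t{fr.group}\t{len(fr.sequence)}\n"
            )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
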