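"""Readers and writers: FASTA sequences, BED-style intervals, motif matrices
and mosaic-model parameter files.

Coordinates are 0-based half-open throughout (BED-native); any 1-based
display is formatting only.  All reader/writer pairs round-trip losslessly
on valid files.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hmm import MosaicModel, ModelError
from .motifs import MotifMatrix

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    pass


@dataclass
class SeqRecord:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Interval:
    """0-based half-open interval, optionally stranded and labelled."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    label: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
#
# A purpose-built strict reader: the contract here (uppercase normalization,
# {A,C,G,T,N} alphabet enforcement and line-numbered parse errors) is part of
# the pipeline's validation surface.

def read_fasta(path) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(_lineno: int = 0) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"line {header_line}: record {header!r} has an "
                             "empty sequence")
        records.append(SeqRecord(header, seq))
        header, chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
            else:
                if header is None:
                    raise ParseError(
                        f"line {lineno}: sequence data before any header")
                up = line.upper()
                bad = set(up) - VALID_BASES
                if bad:
                    raise ParseError(
                        f"line {lineno}: invalid character(s) "
                        f"{sorted(bad)} in sequence {header!r}")
                chunks.append(up)
    flush(header_line)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED intervals

def read_intervals(path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 tab-separated "
                                 f"columns, got {len(cols)}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate "
                                 f"({exc})") from None
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            label = cols[3] if len(cols) > 3 else "."
            strand = cols[5] if len(cols) > 5 else "."
            try:
                out.append(Interval(cols[0], start, end, strand, label))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    return out


def write_intervals(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t"
                     f"{iv.strand}\n")


def extract(interval: Interval, genome: dict[str, str]) -> str:
    """Sequence of an interval; always returns exactly ``interval.length``
    characters or raises."""
    seq = genome[interval.seq_id]
    if interval.end > len(seq):
        raise ValueError(f"interval {interval.seq_id}:{interval.start}-"
                         f"{interval.end} exceeds sequence length {len(seq)}")
    return seq[interval.start:interval.end]


# ---------------------------------------------------------------------------
# motif matrices
#
# Minimal text format: optional '#' comments, an optional
# "background: pA pC pG pT" line, then one row of four probabilities
# (A C G T) per motif position.

def read_motif(path) -> MotifMatrix:
    rows = []
    background = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", ">")):
                continue
            if line.lower().startswith("background:"):
                vals = line.split(":", 1)[1].split()
                background = np.array([float(v) for v in vals])
                continue
            vals = line.split()
            if len(vals) != 4:
                raise ParseError(f"line {lineno}: expected 4 probabilities, "
                                 f"got {len(vals)}")
            row = np.array([float(v) for v in vals])
            if (row < 0).any():
                raise ParseError(f"line {lineno}: negative probability")
            if abs(row.sum() - 1.0) > 1e-6:
                raise ParseError(f"line {lineno}: row sums to {row.sum():.6g},"
                                 " not 1")
            rows.append(row)
    if not rows:
        raise ParseError("motif file contains no probability rows")
    return MotifMatrix(np.stack(rows), background=background)


def write_motif(motif: MotifMatrix, path, name: str = "motif") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {name}, width {motif.width}, columns A C G T\n")
        fh.write("background: " + " ".join(f"{v:.17g}"
                                           for v in motif.background) + "\n")
        for row in motif.probs:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# model parameter files
#
# This package's own text format.  Layout (comments start with '#'):
#   K <n_states>
#   pair <1-based partner of each state>    (classes a, b of pair n are
#                                            states 2n-1 and 2n by default)
#   pi <K values>
#   A                                        (K rows of K values)
#   e0                                       (K rows of 4 values)
#   E state <s>                              (K blocks of 4 rows of 4 values,
#                                            row = previous base A,C,G,T)

def write_model(model: MosaicModel, path, comment: str = "") -> None:
    def fmt(vals):
        return " ".join(f"{v:.17g}" for v in vals)

    with open(path, "w") as fh:
        fh.write("# mosaic-class HMM parameter file\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"K {model.K}\n")
        fh.write("pair " + " ".join(str(int(p) + 1) for p in model.pair) + "\n")
        fh.write("pi " + fmt(model.pi) + "\n")
        fh.write("A\n")
        for row in model.A:
            fh.write(fmt(row) + "\n")
        fh.write("e0\n")
        for row in model.e0:
            fh.write(fmt(row) + "\n")
        for s in range(model.K):
            fh.write(f"E state {s + 1}\n")
            for row in model.E[s]:
                fh.write(fmt(row) + "\n")


def read_model(path) -> MosaicModel:
    lines = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                lines.append(line)
    it = iter(lines)

    def take() -> str:
        try:
            return next(it)
        except StopIteration:
            raise ParseError("unexpected end of model file") from None

    head = take().split()
    if head[0] != "K":
        raise ParseError("model file must start with a K line")
    K = int(head[1])
    if K % 2:
        raise ModelError(f"odd state count {K}")
    pair_line = take().split()
    if pair_line[0] != "pair":
        raise ParseError("expected pair line")
    pair = np.array([int(v) - 1 for v in pair_line[1:]], dtype=np.int64)
    pi_line = take().split()
    if pi_line[0] != "pi":
        raise ParseError("expected pi line")
    pi = np.array([float(v) for v in pi_line[1:]])

    def matrix(n_rows: int, n_cols: int) -> np.ndarray:
        rows = []
        for _ in range(n_rows):
            vals = [float(v) for v in take().split()]
            if len(vals) != n_cols:
                raise ParseError(f"expected {n_cols} values per row")
            rows.append(vals)
        return np.array(rows)

    if take() != "A":
        raise ParseError("expected A block")
    A = matrix(K, K)
    if take() != "e0":
        raise ParseError("expected e0 block")
    e0 = matrix(K, 4)
    E = np.empty((K, 4, 4))
    for s in range(K):
        tag = take().split()
        if tag[:2] != ["E", "state"] or int(tag[2]) != s + 1:
            raise ParseError(f"expected 'E state {s + 1}' block")
        E[s] = matrix(4, 4)
    model = MosaicModel(pi, A, E, e0, pair)
    try:
        model.validate(atol=1e-6, symmetry=False)
    except ModelError:
        raise
    return model
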