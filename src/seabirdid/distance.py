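"""Alignment and uncorrected ("raw") pairwise distance computation.

Identification uses p-distances: the fraction of differing sites among
compared sites, with no substitution-model correction. Sites where either
sequence has a gap or an ambiguity code are excluded pair by pair
(pairwise deletion), which is conservative for degraded feather reads —
an N never counts as a match. Reference alignments are built with a
deterministic center-star strategy (every sequence is globally aligned,
free end gaps, to the longest reference and gap patterns are merged), and
queries are placed onto the finished alignment as a fixed profile so short
fragments overlap only part of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd
from Bio import Align

from .errors import UnalignableQueryError, ValidationError
from .refdb import ReferenceDatabase

DEFAULT_MIN_OVERLAP = 100
#: Minimum identity to the closest reference for a query to count as placed.
DEFAULT_IDENTITY_FLOOR = 0.75

_BASES = frozenset(b"ACGT")


@dataclass(frozen=True)
class AlignmentScoring:
    """Pairwise alignment scores (free end gaps are always applied)."""

    match: float = 2.0
    mismatch: float = -1.0
    open_gap: float = -5.0
    extend_gap: float = -1.0


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.open_gap
    aligner.extend_gap_score = scoring.extend_gap
    # free end gaps: fragments may cover only part of the marker
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


@dataclass
class MarkerAlignment:
    """A multiple alignment of one marker's reference sequences.

    ``rows`` maps accession to its gapped row; all rows share
    ``n_columns`` and gap-stripping a row reproduces the stored sequence.
    """

    marker_id: str
    rows: dict[str, str]
    n_columns: int
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def __post_init__(self) -> None:
        for acc, row in self.rows.items():
            if len(row) != self.n_columns:
                raise ValidationError(
                    f"row {acc} has {len(row)} columns, expected {self.n_columns}"
                )

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, accession: str) -> str:
        return self.rows[accession].replace("-", "")


def _pairwise(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _gap_profile(center_row: str, other_row: str, m: int) -> tuple[list[int], list[list[str]], list[str]]:
    """Decompose a pairwise alignment against the center sequence.

    Returns (ins[i]: gap-run length before center base i, for i in 0..m;
    blocks[i]: the other row's characters in that gap run; aligned[i]: the
    other row's character over center base i).
    """
    ins = [0] * (m + 1)
    blocks: list[list[str]] = [[] for _ in range(m + 1)]
    aligned = ["-"] * m
    i = 0
    for c_char, o_char in zip(center_row, other_row):
        if c_char == "-":
            ins[i] += 1
            blocks[i].append(o_char)
        else:
            aligned[i] = o_char
            i += 1
    return ins, blocks, aligned


def build_marker_alignment(
    db: ReferenceDatabase, scoring: AlignmentScoring | None = None
) -> MarkerAlignment:
    """Center-star progressive alignment of all active records.

    The longest active sequence (ties broken by accession) is the center;
    every other sequence is globally aligned to it with free end gaps and
    the per-sequence gap patterns are merged into shared columns.
    Deterministic: rows are emitted in lexicographic accession order.
    """
    scoring = scoring or AlignmentScoring()
    records = sorted(db.active_records, key=lambda r: r.accession)
    if len(records) < 2:
        raise ValidationError("need at least 2 active records to build an alignment")
    center = min(records, key=lambda r: (-len(r.sequence), r.accession))
    m = len(center.sequence)
    aligner = _make_aligner(scoring)

    per_seq: dict[str, tuple[list[int], list[list[str]], list[str]]] = {}
    ins_max = [0] * (m + 1)
    for rec in records:
        if rec.accession == center.accession:
            continue
        c_row, o_row = _pairwise(aligner, center.sequence, rec.sequence)
        prof = _gap_profile(c_row, o_row, m)
        per_seq[rec.accession] = prof
        for i, v in enumerate(prof[0]):
            ins_max[i] = max(ins_max[i], v)

    def rebuild(ins: list[int], blocks: list[list[str]], aligned: list[str]) -> str:
        out: list[str] = []
        for i in range(m + 1):
            block = blocks[i]
            out.append("".join(block) + "-" * (ins_max[i] - len(block)))
            if i < m:
                out.append(aligned[i])
        return "".join(out)

    rows: dict[str, str] = {}
    center_prof = ([0] * (m + 1), [[] for _ in range(m + 1)], list(center.sequence))
    for rec in records:
        prof = center_prof if rec.accession == center.accession else per_seq[rec.accession]
        rows[rec.accession] = rebuild(*prof)

    n_columns = m + sum(ins_max)
    return MarkerAlignment(
        marker_id=db.marker_id, rows=rows, n_columns=n_columns, scoring=scoring
    )


def align_query(
    query: str,
    alignment: MarkerAlignment,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> str:
    """Place a query onto the alignment treated as a fixed profile.

    The query is pairwise-aligned (free end gaps) to every reference
    sequence; the best-scoring reference anchors the placement, and the
    query's bases are projected into that reference's columns. Insertions
    relative to the profile are dropped — columns are immutable. A query
    that overlaps fewer than ``min_overlap`` non-gap columns with every
    reference, or whose identity to its closest reference is below
    ``identity_floor``, raises :class:`UnalignableQueryError`.
    """
    query = query.upper()
    if len(query) < DEFAULT_MIN_OVERLAP:
        raise UnalignableQueryError(
            f"query length {len(query)} below minimum {DEFAULT_MIN_OVERLAP}"
        )
    aligner = _make_aligner(alignment.scoring)

    best: tuple[float, str] | None = None  # (score, accession)
    for acc in alignment.ids:
        score = aligner.score(alignment.ungapped(acc), query)
        if best is None or score > best[0] or (score == best[0] and acc < best[1]):
            best = (score, acc)
    assert best is not None
    ref_acc = best[1]
    ref_seq = alignment.ungapped(ref_acc)
    ref_row = alignment.rows[ref_acc]

    # column index of each reference base in the master alignment
    base_cols = [i for i, ch in enumerate(ref_row) if ch != "-"]

    r_row, q_row = _pairwise(aligner, ref_seq, query)
    out = ["-"] * alignment.n_columns
    ref_i = 0
    for r_char, q_char in zip(r_row, q_row):
        if r_char != "-":
            if q_char != "-":
                out[base_cols[ref_i]] = q_char
            ref_i += 1
        # q_char aligned to a reference gap is an insertion: dropped
    placed = "".join(out)

    # overlap / identity checks against the profile
    q_arr = np.frombuffer(placed.encode(), dtype="S1")
    best_overlap = 0
    best_identity = 0.0
    for acc in alignment.ids:
        r_arr = np.frombuffer(alignment.rows[acc].encode(), dtype="S1")
        both = (q_arr != b"-") & (r_arr != b"-")
        overlap = int(both.sum())
        best_overlap = max(best_overlap, overlap)
        if overlap:
            ident = float((q_arr[both] == r_arr[both]).sum() / overlap)
            best_identity = max(best_identity, ident)
    if best_overlap < min_overlap:
        raise UnalignableQueryError(
            f"query overlaps at most {best_overlap} columns with any reference "
            f"(minimum {min_overlap})"
        )
    if best_identity < identity_floor:
        raise UnalignableQueryError(
            f"query identity to closest reference {best_identity:.2f} below "
            f"floor {identity_floor:.2f}"
        )
    return placed


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def _encode(row: str) -> np.ndarray:
    return np.frombuffer(row.upper().encode(), dtype=np.uint8)


_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID[_b] = True


def p_distance(
    a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[float, int]:
    """Uncorrected distance between two aligned rows.

    Compared sites are the columns where both rows carry an unambiguous
    base (A, C, G or T); gaps and ambiguity codes are deleted pairwise.
    Returns ``(mismatches / n_compared, n_compared)``, or ``(nan, n)``
    when fewer than ``min_overlap`` sites are comparable.
    """
    xa, xb = _encode(a), _encode(b)
    if len(xa) != len(xb):
        raise ValidationError("rows come from different alignments (length mismatch)")
    valid = _VALID[xa] & _VALID[xb]
    n = int(valid.sum())
    if n < min_overlap or n == 0:
        return (float("nan"), n)
    mism = int(((xa != xb) & valid).sum())
    return (mism / n, n)


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected-distance matrix with per-pair overlap counts.

    Entries whose comparable-site count fell below the overlap floor are
    ``nan`` ("missing"); classification treats them as above any
    threshold.
    """

    ids: list[str]
    d: np.ndarray
    n_compared: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_compared.shape != (n, n):
            raise ValidationError("matrix shapes do not match id count")

    def index(self, accession: str) -> int:
        try:
            return self.ids.index(accession)
        except ValueError:
            raise KeyError(accession) from None

    def to_tsv(self, path: str | Path | TextIO) -> None:
        df = pd.DataFrame(self.d, index=self.ids, columns=self.ids)
        df.index.name = "ids"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path | TextIO) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="ids", na_values="NA")
        ids = [str(i) for i in df.index]
        d = df.to_numpy(dtype=float)
        n = np.zeros_like(d, dtype=int)  # overlap counts are not serialized
        return cls(ids=ids, d=d, n_compared=n)


def distance_matrix(
    alignment: MarkerAlignment,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """All-pairs p-distances for an alignment.

    ``deletion`` is ``"pairwise"`` (default: sites deleted pair by pair)
    or ``"complete"`` (columns with any gap/ambiguity in any row are
    removed once, before all comparisons).
    """
    if deletion not in ("pairwise", "complete"):
        raise ValidationError(f"unknown deletion mode {deletion!r}")
    ids = alignment.ids
    if len(ids) < 2:
        raise ValidationError("need at least 2 rows")
    mat = np.vstack([_encode(alignment.rows[acc]) for acc in ids])
    valid = _VALID[mat]
    if deletion == "complete":
        keep = valid.all(axis=0)
        mat = mat[:, keep]
        valid = valid[:, keep]
    n = len(ids)
    d = np.zeros((n, n), dtype=float)
    nc = np.zeros((n, n), dtype=int)
    for i in range(n):
        vi, xi = valid[i], mat[i]
        both = vi & valid[i + 1 :]
        counts = both.sum(axis=1)
        mism = ((xi != mat[i + 1 :]) & both).sum(axis=1)
        for off, (cnt, ms) in enumerate(zip(counts, mism)):
            j = i + 1 + off
            nc[i, j] = nc[j, i] = int(cnt)
            val = ms / cnt if cnt >= min_overlap and cnt > 0 else float("nan")
            d[i, j] = d[j, i] = val
        nc[i, i] = int(vi.sum())
    return DistanceMatrix(ids=list(ids), d=d, n_compared=nc)


def write_alignment_fasta(alignment: MarkerAlignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in alignment.ids:
            fh.write(f">{acc}\n")
            row = alignment.rows[acc]
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")
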