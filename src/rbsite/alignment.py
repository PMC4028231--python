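"""Pairwise local alignments, the six alignment statistics, and the IC score.

The interface-conservation (IC) score of a query/homolog pair measures how
well the homolog's experimentally known interface residues predict the
query's: it is the correlation coefficient of the two aligned binary interface
label vectors (equivalently, the Matthews correlation of the homolog labels
treated as predictions of the query labels over the aligned columns).

Six statistics summarise the quality of a local alignment: positive score
PS = positives / L, identity score IS = identities / L, −log10(E-value),
log10(L), and the alignment-length fractions L/LQ and L/LH.  They are the
predictors from which the IC score of a novel pair is estimated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .structures import UNRESOLVED

logger = logging.getLogger(__name__)

#: −log10(E) used when BLAST reports E = 0 (underflow).
DEFAULT_E_CAP = 200.0


@dataclass
class PairwiseAlignment:
    """A local alignment between a query and a homolog with BLAST statistics.

    ``position_map`` lists the aligned (query_pos, homolog_pos) column pairs,
    1-based, gap columns absent, strictly increasing in both coordinates.
    """

    query_id: str
    homolog_id: str
    position_map: list[tuple[int, int]]
    e_value: float
    length: int
    identities: int
    positives: int
    query_length: int
    homolog_length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("local alignment length must be >= 1")
        if not (0 <= self.identities <= self.positives <= self.length):
            raise ValueError("need 0 <= identities <= positives <= L")
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")
        qs = [q for q, _ in self.position_map]
        hs = [h for _, h in self.position_map]
        if any(b <= a for a, b in zip(qs, qs[1:])) or any(
            b <= a for a, b in zip(hs, hs[1:])
        ):
            raise ValueError("position_map must be strictly increasing in both coordinates")
        if self.position_map:
            if not (1 <= qs[0] and qs[-1] <= self.query_length):
                raise ValueError("mapped query positions out of range")
            if not (1 <= hs[0] and hs[-1] <= self.homolog_length):
                raise ValueError("mapped homolog positions out of range")


@dataclass
class AlignmentStatistics:
    """The six alignment statistics of a query/homolog pair."""

    positive_score: float
    identity_score: float
    neg_log_e: float
    log_l: float
    frac_query: float
    frac_homolog: float
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_score <= self.positive_score <= 1.0:
            raise ValueError("need 0 <= IS <= PS <= 1")
        if not (0.0 < self.frac_query <= 1.0 and 0.0 < self.frac_homolog <= 1.0):
            raise ValueError("length fractions must lie in (0, 1]")

    @property
    def length_fraction(self) -> float:
        """Single length-fraction predictor: L relative to the shorter chain."""
        return max(self.frac_query, self.frac_homolog)


def compute_statistics(
    aln: PairwiseAlignment,
    e_cap: float = DEFAULT_E_CAP,
    log_base: float = 10.0,
) -> AlignmentStatistics:
    """Compute the six alignment statistics for one alignment.

    An E-value of exactly 0 (BLAST underflow) maps to ``neg_log_e = e_cap``;
    a pathological L exceeding a chain length caps the fraction at 1 with a
    warning.
    """
    if aln.query_length < 1 or aln.homolog_length < 1:
        raise ValueError("chain lengths must be >= 1")
    if aln.e_value == 0.0:
        neg_log_e = float(e_cap)
    else:
        neg_log_e = min(float(e_cap), -math.log(aln.e_value, log_base))
    frac_q = aln.length / aln.query_length
    frac_h = aln.length / aln.homolog_length
    if frac_q > 1.0 or frac_h > 1.0:
        logger.warning(
            "alignment %s/%s longer than a chain; fraction capped at 1",
            aln.query_id,
            aln.homolog_id,
        )
        frac_q, frac_h = min(frac_q, 1.0), min(frac_h, 1.0)
    return AlignmentStatistics(
        positive_score=aln.positives / aln.length,
        identity_score=aln.identities / aln.length,
        neg_log_e=neg_log_e,
        log_l=math.log(aln.length, log_base),
        frac_query=frac_q,
        frac_homolog=frac_h,
        log_base=log_base,
    )


# ---------------------------------------------------------------------------
# IC score
# ---------------------------------------------------------------------------

@dataclass
class ICScoreResult:
    """IC score with a flag for degenerate (constant-vector) pairs."""

    value: float
    degenerate: bool = False
    n_columns: int = 0


def ic_score(
    query_labels,
    homolog_labels,
    mask_unresolved: bool = True,
) -> ICScoreResult:
    """Interface-conservation score of two aligned binary label vectors.

    Pearson correlation of the aligned 0/1 interface indicators; for vectors
    containing both classes this equals the Matthews correlation of the 2×2
    aligned-label contingency table.  Columns where either residue is
    unresolved (label −1) are excluded when ``mask_unresolved`` is true.
    Constant vectors carry no conservation signal: the score is 0 with
    ``degenerate=True``.

    Raises
    ------
    ValueError
        On length mismatch, or when no comparable columns remain after
        masking.
    """
    q = np.asarray(query_labels, dtype=int)
    h = np.asarray(homolog_labels, dtype=int)
    if q.shape != h.shape:
        raise ValueError("label vectors must have equal length")
    if mask_unresolved:
        keep = (q != UNRESOLVED) & (h != UNRESOLVED)
        q, h = q[keep], h[keep]
    if q.size == 0:
        raise ValueError("no comparable columns")
    if np.all(q == q[0]) or np.all(h == h[0]):
        return ICScoreResult(0.0, degenerate=True, n_columns=int(q.size))
    # phi coefficient of the 2×2 contingency table: equals the Pearson
    # correlation of the 0/1 vectors, and is exact (±1) at the boundaries
    tp = int(np.sum((q == 1) & (h == 1)))
    fp = int(np.sum((q == 0) & (h == 1)))
    fn = int(np.sum((q == 1) & (h == 0)))
    tn = int(np.sum((q == 0) & (h == 0)))
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return ICScoreResult(num / den, degenerate=False, n_columns=int(q.size))


# ---------------------------------------------------------------------------
# Alignment I/O: BLAST tabular / XML, and the internal alignment table
# ---------------------------------------------------------------------------

#: Column layout of the internal alignment table (TSV).  ``qseq``/``sseq`` are
#: the gapped aligned strings from which the position map is reconstructed.
TABLE_COLUMNS = [
    "qseqid", "sseqid", "evalue", "length", "nident", "positive",
    "qlen", "slen", "qstart", "sstart", "qseq", "sseq",
]


def _map_from_gapped(qseq: str, sseq: str, qstart: int, sstart: int) -> list[tuple[int, int]]:
    if len(qseq) != len(sseq):
        raise ValueError("gapped aligned strings differ in length")
    out: list[tuple[int, int]] = []
    qpos, spos = qstart - 1, sstart - 1
    for qc, sc in zip(qseq, sseq):
        qgap, sgap = qc == "-", sc == "-"
        if not qgap:
            qpos += 1
        if not sgap:
            spos += 1
        if not qgap and not sgap:
            out.append((qpos, spos))
    return out


def _row_to_alignment(row: dict[str, str]) -> PairwiseAlignment:
    return PairwiseAlignment(
        query_id=row["qseqid"],
        homolog_id=row["sseqid"],
        position_map=_map_from_gapped(
            row["qseq"], row["sseq"], int(row["qstart"]), int(row["sstart"])
        ),
        e_value=float(row["evalue"]),
        length=int(row["length"]),
        identities=int(row["nident"]),
        positives=int(row["positive"]),
        query_length=int(row["qlen"]),
        homolog_length=int(row["slen"]),
    )


def read_alignment_table(path: str | Path) -> list[PairwiseAlignment]:
    """Read the internal TSV alignment table (also BLAST outfmt 6 with the
    matching custom column list and a leading header line)."""
    out: list[PairwiseAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").strip().split("\t")
        if header != TABLE_COLUMNS:
            raise ValueError(
                f"unexpected alignment-table columns {header}; expected {TABLE_COLUMNS}"
            )
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(TABLE_COLUMNS, line.rstrip("\n").split("\t")))
            out.append(_row_to_alignment(row))
    return out


def write_alignment_table(alignments: Iterable[PairwiseAlignment], path: str | Path) -> None:
    """Write alignments as the internal TSV table.

    The gapped strings are emitted as match/gap skeletons ('X'/'-') built from
    the position map; statistics round-trip exactly, residue identities are
    not stored here (they live in the FASTA/labels files).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for aln in alignments:
            qseq, sseq = _gapped_from_map(aln.position_map)
            qstart = aln.position_map[0][0] if aln.position_map else 1
            sstart = aln.position_map[0][1] if aln.position_map else 1
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        aln.query_id, aln.homolog_id, repr(aln.e_value), aln.length,
                        aln.identities, aln.positives, aln.query_length,
                        aln.homolog_length, qstart, sstart, qseq, sseq,
                    ]
                )
                + "\n"
            )


def _gapped_from_map(position_map: list[tuple[int, int]]) -> tuple[str, str]:
    if not position_map:
        return "", ""
    q_parts: list[str] = []
    s_parts: list[str] = []
    pq, ps = position_map[0]
    q_parts.append("X")
    s_parts.append("X")
    for q, s in position_map[1:]:
        dq, ds = q - pq, s - ps
        # unaligned stretches on either side become gap columns
        q_parts.append("X" * (dq - 1) + "-" * (ds - 1) + "X")
        s_parts.append("-" * (dq - 1) + "X" * (ds - 1) + "X")
        pq, ps = q, s
    return "".join(q_parts), "".join(s_parts)


def read_blast_xml(path: str | Path, homolog_lengths: dict[str, int] | None = None) -> list[PairwiseAlignment]:
    """Parse BLAST XML output into alignments (one per HSP)."""
    from Bio.Blast import NCBIXML

    out: list[PairwiseAlignment] = []
    with open(path) as fh:
        for record in NCBIXML.parse(fh):
            for alignment in record.alignments:
                if alignment.hit_def and not alignment.hit_def.startswith("No definition"):
                    sid = alignment.hit_def.split()[0]
                else:
                    sid = alignment.accession or alignment.hit_id
                slen = alignment.length
                if homolog_lengths and sid in homolog_lengths:
                    slen = homolog_lengths[sid]
                for hsp in alignment.hsps:
                    out.append(
                        PairwiseAlignment(
                            query_id=record.query.split()[0],
                            homolog_id=sid,
                            position_map=_map_from_gapped(
                                hsp.query, hsp.sbjct, hsp.query_start, hsp.sbjct_start
                            ),
                            e_value=hsp.expect,
                            length=hsp.align_length,
                            identities=hsp.identities,
                            positives=hsp.positives,
                            query_length=record.query_length,
                            homolog_length=slen,
                        )
                    )
    return out
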