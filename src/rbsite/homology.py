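"""Homology-based interface prediction by weighted label transfer.

Given BLAST-style hits of a query against a database of RNA-binding protein
chains with experimentally known interface residues, each hit is weighted by
its predicted IC score and assigned a homology zone.  Hits nearly identical
to the query (positive score above a similarity-exclusion cutoff, default
0.95) are discarded first; then the best non-empty zone is used: all Safe
hits if any exist, otherwise all Twilight, otherwise all Dark.  Each query
position aligned in at least one selected homolog receives the weighted mean
of that position's homolog interface indicators:

    P_i = Σ_k w_k · v_ik / Σ_k w_k          (over homologs aligned at i)

with v_ik = 1 iff the residue aligned to i in homolog k is an interface
residue.  P_i ≥ 0.5 (by default) is called interface.  Positions aligned in
no selected homolog — and whole queries with no selectable hit — stay
MISSING; the hybrid stage fills those in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment import AlignmentStatistics, PairwiseAlignment, compute_statistics
from .ic_model import ICModel, Zone, ZoneThresholds, assign_zone, predict_ic
from .structures import INTERFACE, UNRESOLVED

logger = logging.getLogger(__name__)

#: Per-residue scores/calls use NaN for MISSING.
MISSING = float("nan")


@dataclass
class HomologHit:
    """A database hit annotated with predicted IC and homology zone."""

    alignment: PairwiseAlignment
    stats: AlignmentStatistics
    predicted_ic: float
    zone: Zone
    homolog_labels: np.ndarray

    def __post_init__(self) -> None:
        self.homolog_labels = np.asarray(self.homolog_labels, dtype=int)
        if len(self.homolog_labels) != self.alignment.homolog_length:
            raise ValueError("homolog_labels length must equal homolog_length")

    @classmethod
    def from_alignment(
        cls,
        alignment: PairwiseAlignment,
        homolog_labels,
        model: ICModel | None = None,
        thresholds: ZoneThresholds | None = None,
    ) -> "HomologHit":
        stats = compute_statistics(alignment)
        w = predict_ic(stats, model)
        return cls(alignment, stats, w, assign_zone(w, thresholds), homolog_labels)


@dataclass
class HomologyResult:
    """Per-residue homology-transfer prediction for one query.

    ``scores``/``calls`` are float arrays of the query length with NaN at
    positions no selected homolog covers; ``zone_used`` is NONE when the
    query has no usable homolog at all.
    """

    query_id: str
    scores: np.ndarray
    calls: np.ndarray
    zone_used: Zone
    homologs_used: list[HomologHit] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        """Fraction of query residues with a defined score."""
        return float(np.mean(~np.isnan(self.scores)))


def dedupe_hsps(hits: Sequence[HomologHit]) -> list[HomologHit]:
    """Keep one HSP per query/homolog pair: highest predicted IC, ties broken
    by lower E-value, then first occurrence."""
    best: dict[tuple[str, str], tuple[float, float, int, HomologHit]] = {}
    for order, hit in enumerate(hits):
        key = (hit.alignment.query_id, hit.alignment.homolog_id)
        rank = (-hit.predicted_ic, hit.alignment.e_value, order)
        if key not in best or rank < best[key][:3]:
            best[key] = (*rank, hit)
    kept = sorted(best.values(), key=lambda t: t[2])
    return [t[3] for t in kept]


def select_homologs(
    hits: Sequence[HomologHit],
    similarity_exclusion: float = 0.95,
    use_identity: bool = False,
) -> tuple[list[HomologHit], Zone]:
    """Pick the hits to vote: exclude near-identical ones, then take the best
    non-empty zone (Safe ≻ Twilight ≻ Dark).

    ``similarity_exclusion`` removes hits whose positive score (or identity
    score with ``use_identity``) exceeds the cutoff, so the query cannot vote
    for itself.  An empty return with zone NONE is a valid "no prediction".
    """
    if not 0.0 < similarity_exclusion <= 1.0:
        raise ValueError("similarity_exclusion must lie in (0, 1]")
    retained = [
        h
        for h in hits
        if (h.stats.identity_score if use_identity else h.stats.positive_score)
        <= similarity_exclusion
    ]
    for zone in (Zone.SAFE, Zone.TWILIGHT, Zone.DARK):
        chosen = [h for h in retained if h.zone == zone]
        if chosen:
            return chosen, zone
    return [], Zone.NONE


def weighted_vote(query_length: int, homologs: Sequence[HomologHit]) -> np.ndarray:
    """Weighted-mean interface vote per query position.

    The denominator at each position sums only over the homologs aligned
    there, so coverage differences do not dilute the vote.  Columns aligned
    to an unresolved homolog residue are skipped.  Positions covered by no
    homolog (or with non-positive total weight) are NaN.
    """
    if not homologs:
        raise ValueError("need at least one homolog to vote")
    num = np.zeros(query_length)
    den = np.zeros(query_length)
    for hit in homologs:
        w = hit.predicted_ic
        for qpos, hpos in hit.alignment.position_map:
            lab = hit.homolog_labels[hpos - 1]
            if lab == UNRESOLVED:
                continue
            num[qpos - 1] += w * (lab == INTERFACE)
            den[qpos - 1] += w
    scores = np.full(query_length, MISSING)
    covered = den > 0
    if np.any(~covered & (np.abs(den) > 0)):
        logger.warning("positions with non-positive total vote weight left MISSING")
    scores[covered] = num[covered] / den[covered]
    return scores


def binarize(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary calls from vote scores; the threshold is inclusive (P ≥ t → 1)
    and NaN (MISSING) propagates."""
    scores = np.asarray(scores, dtype=float)
    calls = np.full(scores.shape, MISSING)
    defined = ~np.isnan(scores)
    calls[defined] = (scores[defined] >= threshold).astype(float)
    return calls


def predict_query(
    query_id: str,
    query_length: int,
    hits: Sequence[HomologHit],
    similarity_exclusion: float = 0.95,
    vote_threshold: float = 0.5,
    use_identity: bool = False,
) -> HomologyResult:
    """Full homology-transfer prediction for one query."""
    unique = dedupe_hsps(hits)
    chosen, zone = select_homologs(unique, similarity_exclusion, use_identity)
    if not chosen:
        empty = np.full(query_length, MISSING)
        return HomologyResult(query_id, empty, empty.copy(), Zone.NONE, [])
    scores = weighted_vote(query_length, chosen)
    return HomologyResult(query_id, scores, binarize(scores, vote_threshold), zone, chosen)


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def write_prediction_table(result: HomologyResult, sequence: str, path: str | Path) -> None:
    """Per-residue TSV: position, amino_acid, score|NA, call|NA, zone_used."""
    with open(path, "w") as fh:
        fh.write("position\tamino_acid\thomology_score\thomology_call\tzone_used\n")
        for i, aa in enumerate(sequence):
            s, c = result.scores[i], result.calls[i]
            fh.write(
                f"{i + 1}\t{aa}\t"
                f"{'NA' if np.isnan(s) else f'{s:.6f}'}\t"
                f"{'NA' if np.isnan(c) else int(c)}\t"
                f"{result.zone_used.name}\n"
            )


def write_homolog_report(hits: Iterable[HomologHit], path: str | Path) -> None:
    """Homolog report TSV: homolog_id, E-value, PS, predicted IC, zone."""
    with open(path, "w") as fh:
        fh.write("homolog_id\tevalue\tpositive_score\tpredicted_ic\tzone\n")
        for h in hits:
            fh.write(
                f"{h.alignment.homolog_id}\t{h.alignment.e_value:g}\t"
                f"{h.stats.positive_score:.4f}\t{h.predicted_ic:.4f}\t{h.zone.name}\n"
            )
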