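"""Taxonomic assignment from top BLAST hits: TopHit, TopHitPlus, TopN,
TopNPlus, with per-rank identity and consensus scores.

Two descriptive statistics underpin all four methods.  The *consensus
score* of a taxon at a rank is the percentage of the considered hits
matching that taxon (e.g. ten hits mapping to two *Brassica napus*,
six *Brassica nigra* and two *Sinapis alba* give a species consensus
of 60% for *B. nigra*, 80% for the genus *Brassica* and 100% for the
family *Brassicaceae*).  The *identity score* attributed to an
assigned taxon is the percent identity (pident) of the
maximum-bit-score hit matching that taxon — not necessarily the
maximum pident, because the bit score penalises short alignments
(98% identity over 400 bp beats 100% over 50 bp).

The four methods:

* **TopHit** — the lineage of the single best-bit-score hit at every rank.
* **TopHitPlus** — like TopHit, but exact bit-score ties are broken by
  the taxon with the highest consensus among the tied hits.
* **TopN** — per rank independently, the taxon with the highest
  consensus among the top hits (ranks may disagree by design).
* **TopNPlus** — like TopN after first discarding hits that fail
  per-rank quality thresholds (alignment length, E-value, identity
  floor, identity distance to the best hit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .search import HitRecord
from .taxonomy import UNKNOWN, TaxonLineage

#: Ranks at which assignments are evaluated.
EVAL_RANKS: tuple[str, ...] = ("family", "genus", "species")

METHOD_NAMES: tuple[str, ...] = ("TopHit", "TopHitPlus", "TopN", "TopNPlus")

Taxmap = Mapping[str, TaxonLineage]


@dataclass(frozen=True)
class RankAssignment:
    """Predicted taxon at one rank with its attributed scores.

    ``taxon``, ``identity`` and ``consensus`` are all ``None`` when the
    method makes no prediction at this rank.
    """

    rank: str
    taxon: str | None
    identity: float | None
    consensus: float | None
    method: str

    def __post_init__(self) -> None:
        none_flags = {self.taxon is None, self.identity is None, self.consensus is None}
        if len(none_flags) != 1:
            raise ValueError("taxon, identity and consensus must all be set or all None")
        if self.consensus is not None and not 0 < self.consensus <= 100:
            raise ValueError(f"consensus {self.consensus} outside (0, 100]")

    @property
    def assigned(self) -> bool:
        return self.taxon is not None


@dataclass(frozen=True)
class AssignmentResult:
    """One query's per-rank assignments under one method."""

    query_id: str
    method: str
    ranks: tuple[RankAssignment, ...]

    def at(self, rank: str) -> RankAssignment:
        for ra in self.ranks:
            if ra.rank == rank:
                return ra
        raise KeyError(rank)


@dataclass(frozen=True)
class TopNPlusParams:
    """Per-rank quality thresholds of the TopNPlus method.

    Defaults: drop hits with alignment length < 100 bp or E-value
    > 1e-10; identity floors 97/90/80% at species/genus/family; and the
    identity of a retained hit must lie strictly within 1/10/20
    percentage points of the best hit's identity.
    """

    min_align_length: int = 100
    max_evalue: float = 1e-10
    identity_floor: Mapping[str, float] = field(
        default_factory=lambda: {"species": 97.0, "genus": 90.0, "family": 80.0}
    )
    identity_window: Mapping[str, float] = field(
        default_factory=lambda: {"species": 1.0, "genus": 10.0, "family": 20.0}
    )


def _resolve(taxmap: Taxmap, subject_id: str) -> TaxonLineage:
    try:
        return taxmap[subject_id]
    except KeyError:
        raise KeyError(f"subject {subject_id!r} missing from taxonomy map") from None


def consensus_scores(
    hits: Iterable[HitRecord], taxmap: Taxmap, rank: str
) -> dict[str, float]:
    """Percentage of the considered hits matching each taxon at *rank*.

    The denominator is the number of hits considered; hits whose lineage
    is ``unknown`` at the rank get no entry (so the percentages sum to
    100 only when every hit is rank-known).
    """
    hits = list(hits)
    if not hits:
        raise ValueError("hits must be non-empty")
    counts: dict[str, int] = {}
    for h in hits:
        taxon = _resolve(taxmap, h.subject_id).taxon_at(rank)
        if taxon != UNKNOWN:
            counts[taxon] = counts.get(taxon, 0) + 1
    return {t: 100.0 * c / len(hits) for t, c in counts.items()}


def identity_for_taxon(
    hits: Iterable[HitRecord], taxmap: Taxmap, rank: str, taxon: str
) -> float:
    """pident of the maximum-bit-score hit matching *taxon* at *rank*
    (exact bit-score ties broken by input rank)."""
    matching = [
        h for h in hits if _resolve(taxmap, h.subject_id).taxon_at(rank) == taxon
    ]
    if not matching:
        raise ValueError(f"no hit matches taxon {taxon!r} at rank {rank}")
    best = min(matching, key=lambda h: (-h.bitscore, h.input_rank))
    return best.pident


def _best_hit(hits: list[HitRecord]) -> HitRecord:
    return min(hits, key=lambda h: (-h.bitscore, h.input_rank))


def _unassigned(method: str) -> tuple[RankAssignment, ...]:
    return tuple(RankAssignment(r, None, None, None, method) for r in EVAL_RANKS)


def _assignment(
    method: str,
    rank: str,
    taxon: str | None,
    hits: list[HitRecord],
    taxmap: Taxmap,
    consensus: Mapping[str, float],
) -> RankAssignment:
    if taxon is None or taxon == UNKNOWN:
        return RankAssignment(rank, None, None, None, method)
    return RankAssignment(
        rank,
        taxon,
        identity_for_taxon(hits, taxmap, rank, taxon),
        consensus[taxon],
        method,
    )


def assign_tophit(query_id: str, hits: Iterable[HitRecord], taxmap: Taxmap) -> AssignmentResult:
    """Best-bit-score hit's lineage at every rank (blast's default when a
    single match is kept); exact ties broken by input rank."""
    hits = list(hits)
    if not hits:
        return AssignmentResult(query_id, "TopHit", _unassigned("TopHit"))
    winner = _best_hit(hits)
    lineage = _resolve(taxmap, winner.subject_id)
    ranks = []
    for rank in EVAL_RANKS:
        cons = consensus_scores(hits, taxmap, rank)
        ranks.append(_assignment("TopHit", rank, lineage.taxon_at(rank), hits, taxmap, cons))
    return AssignmentResult(query_id, "TopHit", tuple(ranks))


def assign_tophitplus(query_id: str, hits: Iterable[HitRecord], taxmap: Taxmap) -> AssignmentResult:
    """Best bit score, with ties broken toward the taxon of highest
    consensus among the tied hits (residual ties: alphabetical)."""
    hits = list(hits)
    if not hits:
        return AssignmentResult(query_id, "TopHitPlus", _unassigned("TopHitPlus"))
    best_score = max(h.bitscore for h in hits)
    tied = [h for h in hits if h.bitscore == best_score]
    ranks = []
    for rank in EVAL_RANKS:
        cons = consensus_scores(hits, taxmap, rank)
        candidates = {
            _resolve(taxmap, h.subject_id).taxon_at(rank) for h in tied
        } - {UNKNOWN}
        if not candidates:
            ranks.append(RankAssignment(rank, None, None, None, "TopHitPlus"))
            continue
        taxon = min(candidates, key=lambda t: (-cons[t], t))
        ranks.append(_assignment("TopHitPlus", rank, taxon, hits, taxmap, cons))
    return AssignmentResult(query_id, "TopHitPlus", tuple(ranks))


def _argmax_consensus(
    cons: Mapping[str, float], hits: list[HitRecord], taxmap: Taxmap, rank: str
) -> str | None:
    """Highest consensus; ties broken by higher attributed identity, then
    alphabetically."""
    if not cons:
        return None
    return min(
        cons,
        key=lambda t: (-cons[t], -identity_for_taxon(hits, taxmap, rank, t), t),
    )


def assign_topn(query_id: str, hits: Iterable[HitRecord], taxmap: Taxmap) -> AssignmentResult:
    """Per rank independently, the taxon of highest consensus among the
    top hits.  Cross-rank consistency is deliberately not enforced: the
    winning species may belong to a different genus than the winning
    genus-level taxon."""
    hits = list(hits)
    if not hits:
        return AssignmentResult(query_id, "TopN", _unassigned("TopN"))
    ranks = []
    for rank in EVAL_RANKS:
        cons = consensus_scores(hits, taxmap, rank)
        taxon = _argmax_consensus(cons, hits, taxmap, rank)
        ranks.append(_assignment("TopN", rank, taxon, hits, taxmap, cons))
    return AssignmentResult(query_id, "TopN", tuple(ranks))


def assign_topnplus(
    query_id: str,
    hits: Iterable[HitRecord],
    taxmap: Taxmap,
    params: TopNPlusParams | None = None,
) -> AssignmentResult:
    """TopN over the hits that pass per-rank quality filters.

    Filters, per rank: (1) alignment length and E-value cut-offs;
    (2) identity floor; (3) identity within a strict window below the
    best hit's identity, the best hit being the maximum-bit-score hit of
    the original list (pre-filter); (4) consensus recomputed over the
    survivors.  When no hit survives, no taxon is attributed.
    """
    params = params or TopNPlusParams()
    hits = list(hits)
    if not hits:
        return AssignmentResult(query_id, "TopNPlus", _unassigned("TopNPlus"))
    best_pident = _best_hit(hits).pident
    ranks = []
    for rank in EVAL_RANKS:
        floor = params.identity_floor[rank]
        window = params.identity_window[rank]
        survivors = [
            h
            for h in hits
            if h.align_length >= params.min_align_length
            and h.evalue <= params.max_evalue
            and h.pident >= floor
            and best_pident - h.pident < window
        ]
        if not survivors:
            ranks.append(RankAssignment(rank, None, None, None, "TopNPlus"))
            continue
        cons = consensus_scores(survivors, taxmap, rank)
        taxon = _argmax_consensus(cons, survivors, taxmap, rank)
        ranks.append(_assignment("TopNPlus", rank, taxon, survivors, taxmap, cons))
    return AssignmentResult(query_id, "TopNPlus", tuple(ranks))


_DISPATCH: dict[str, Callable[..., AssignmentResult]] = {
    "TopHit": assign_tophit,
    "TopHitPlus": assign_tophitplus,
    "TopN": assign_topn,
    "TopNPlus": assign_topnplus,
}


def assign(
    method: str,
    query_id: str,
    hits: Iterable[HitRecord],
    taxmap: Taxmap,
    topnplus_params: TopNPlusParams | None = None,
) -> AssignmentResult:
    """Dispatch to one of the four methods by name."""
    if method not in _DISPATCH:
        raise KeyError(f"unknown method {method!r}; expected one of {METHOD_NAMES}")
    if method == "TopNPlus":
        return assign_topnplus(query_id, hits, taxmap, topnplus_params)
    return _DISPATCH[method](query_id, hits, taxmap)


def write_assignments(
    results: Iterable[AssignmentResult], path: str | Path
) -> None:
    """Tab-separated assignment table, one row per query x method; "NA"
    marks unassigned ranks."""
    cols = ["query_id", "method"]
    for rank in EVAL_RANKS:
        cols += [rank, f"{rank}_identity", f"{rank}_consensus"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for res in results:
            row = [res.query_id, res.method]
            for rank in EVAL_RANKS:
                ra = res.at(rank)
                if ra.assigned:
                    row += [ra.taxon, f"{ra.identity:.3f}", f"{ra.consensus:.3f}"]
                else:
                    row += ["NA", "NA", "NA"]
            fh.write("\t".join(row) + "\n")
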