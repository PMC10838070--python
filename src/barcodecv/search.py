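"""Hit tables: BLAST tabular parsing and a built-in alignment backend.

Every assignment method consumes, per query, the top hits ordered by
bit score.  Hits can come from an external ``blastn`` run
(``-outfmt "6 qseqid sseqid pident length evalue bitscore"
-max_target_seqs 10``) or from :func:`naive_search`, a self-contained
Smith–Waterman backend for desk-scale work that mimics blastn tabular
semantics.  Only rank order, ties and percent identity matter to the
downstream logic; the backend's bit-score calibration is documented,
not fitted to NCBI BLAST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import Align

from .refdb import ReferenceDatabase

DEFAULT_MAX_HITS = 10


class BlastFormatError(ValueError):
    """Malformed BLAST tabular input (message carries the line number)."""


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit in blastn outfmt-6 terms.

    ``input_rank`` is the 1-based position in the backend's output order
    for the query; it is the documented tie-break when bit scores are
    exactly equal.
    """

    query_id: str
    subject_id: str
    pident: float
    align_length: int
    evalue: float
    bitscore: float
    input_rank: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.align_length < 1:
            raise ValueError(f"align_length {self.align_length} < 1")
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} < 0")


def canonical_sort(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Total, stable hit order: bit score descending, input rank ascending."""
    return sorted(hits, key=lambda h: (-h.bitscore, h.input_rank))


class HitTable:
    """Per-query ordered lists of :class:`HitRecord`."""

    def __init__(self, hits_by_query: dict[str, list[HitRecord]] | None = None):
        self._hits: dict[str, list[HitRecord]] = hits_by_query or {}

    def queries(self) -> list[str]:
        return list(self._hits)

    def hits(self, query_id: str) -> list[HitRecord]:
        return self._hits.get(query_id, [])

    def __len__(self) -> int:
        return len(self._hits)

    def items(self):
        return self._hits.items()

    def truncated(self, n: int) -> "HitTable":
        """Canonically sorted, per-query truncation to the top *n* hits."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return HitTable(
            {q: canonical_sort(hits)[:n] for q, hits in self._hits.items()}
        )


def top_hits(table: HitTable, n: int = DEFAULT_MAX_HITS) -> HitTable:
    """Keep each query's *n* best hits (bit score desc, input rank asc)."""
    return table.truncated(n)


# ---------------------------------------------------------------------------
# BLAST tabular I/O

def parse_blast_tabular(path: str | Path, max_hits: int | None = DEFAULT_MAX_HITS) -> HitTable:
    """Read outfmt-6 rows (qseqid sseqid pident length evalue bitscore).

    Extra trailing columns are tolerated; an empty file is a valid empty
    table (blast found no match).  Each query's rows get ``input_rank``
    in file order, then the canonical sort and *max_hits* truncation are
    applied.
    """
    hits: dict[str, list[HitRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise BlastFormatError(f"{path}:{lineno}: expected >= 6 columns")
            q, s = parts[0], parts[1]
            try:
                rec = HitRecord(
                    query_id=q,
                    subject_id=s,
                    pident=float(parts[2]),
                    align_length=int(parts[3]),
                    evalue=float(parts[4]),
                    bitscore=float(parts[5]),
                    input_rank=len(hits.get(q, [])) + 1,
                )
            except ValueError as exc:
                raise BlastFormatError(f"{path}:{lineno}: {exc}") from exc
            hits.setdefault(q, []).append(rec)
    table = HitTable(hits)
    return table.truncated(max_hits) if max_hits else table


def write_blast_tabular(table: HitTable, path: str | Path) -> None:
    """Write the six canonical outfmt-6 columns, queries in table order."""
    with open(path, "w") as fh:
        for q in table.queries():
            for h in table.hits(q):
                fh.write(
                    f"{h.query_id}\t{h.subject_id}\t{h.pident:.3f}\t"
                    f"{h.align_length}\t{h.evalue:.3g}\t{h.bitscore:.5g}\n"
                )


# ---------------------------------------------------------------------------
# Built-in search backend

@dataclass(frozen=True)
class SearchParams:
    """Scoring and reporting parameters of the built-in backend.

    Alignment scoring is match +2 / mismatch −3 with gap open −5 and gap
    extension −2 (the first gap position costs the open score).  Raw
    scores S are converted to bits as (λ·S − ln K)/ln 2 with fixed
    λ=0.625, K=0.41, and E = m·n·2^(−bits) with m the query length and n
    the total reference length.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lambda_: float = 0.625
    k: float = 0.41
    max_hits: int = DEFAULT_MAX_HITS
    max_evalue: float = 10.0

    def bitscore(self, raw_score: float) -> float:
        return (self.lambda_ * raw_score - math.log(self.k)) / math.log(2.0)


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def naive_search(
    queries: ReferenceDatabase,
    reference: ReferenceDatabase,
    params: SearchParams | None = None,
) -> HitTable:
    """Align every query against every reference sequence (local
    alignment) and keep each query's top hits by bit score.

    Deterministic: reference load order breaks exact bit-score ties, so
    unique-mode duplicate records appear adjacently in load order.
    """
    if len(queries) == 0 or len(reference) == 0:
        raise ValueError("queries and reference must be non-empty")
    params = params or SearchParams()
    aligner = _make_aligner(params)
    total_ref_len = sum(len(r.sequence) for r in reference)
    out: dict[str, list[HitRecord]] = {}
    for q in queries:
        scored: list[tuple[float, int, str, float, int]] = []
        for order, ref in enumerate(reference.records):
            try:
                # first co-optimal alignment; len() is avoided because the
                # number of co-optimal paths can overflow
                aln = aligner.align(q.sequence, ref.sequence)[0]
            except IndexError:
                continue
            if aln.score <= 0:
                continue
            counts = aln.counts()
            align_length = counts.identities + counts.mismatches + counts.gaps
            if align_length < 1:
                continue
            pident = 100.0 * counts.identities / align_length
            bitscore = params.bitscore(aln.score)
            evalue = len(q.sequence) * total_ref_len * 2.0 ** (-bitscore)
            if evalue > params.max_evalue:
                continue
            scored.append((bitscore, order, ref.seq_id, pident, align_length))
        scored.sort(key=lambda t: (-t[0], t[1]))
        hits = [
            HitRecord(
                query_id=q.seq_id,
                subject_id=seq_id,
                pident=round(pident, 3),
                align_length=align_length,
                evalue=len(q.sequence) * total_ref_len * 2.0 ** (-bitscore),
                bitscore=bitscore,
                input_rank=rank,
            )
            for rank, (bitscore, _, seq_id, pident, align_length) in enumerate(
                scored[: params.max_hits], 1
            )
        ]
        out[q.seq_id] = hits
    return HitTable(out)
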