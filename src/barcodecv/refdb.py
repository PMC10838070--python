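"""Reference-database I/O, Local/World subsetting, target selection and
primer-based amplicon restriction.

A reference database is an ordered collection of barcode sequences,
each joined to a seven-rank lineage and flagged as *local* (present in
the study area's flora) or *foreign*.  Databases are read from a FASTA
file plus a two-column tab-separated taxonomy table (sequence ID,
semicolon-delimited lineage) and written back in the same formats with
deterministic ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import TaxonLineage, is_hybrid, is_imprecise, parse_lineage

logger = logging.getLogger(__name__)

IUPAC_CODES = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

LOCAL = "local"
FOREIGN = "foreign"


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceRecord:
    """One barcode sequence with its lineage and origin flag.

    ``source_accession`` links a primer-restricted sequence back to its
    full-length parent (defaults to the record's own ID); it is what the
    restricted-vs-general cross-validation design uses to purge parents
    from the reference.
    """

    seq_id: str
    sequence: str
    lineage: TaxonLineage
    origin: str = FOREIGN
    source_accession: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = set(seq) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"{self.seq_id}: non-IUPAC characters {sorted(bad)}")
        if self.origin not in (LOCAL, FOREIGN):
            raise ValueError(f"{self.seq_id}: origin must be local/foreign")
        if self.source_accession is None:
            object.__setattr__(self, "source_accession", self.seq_id)

    @property
    def species(self) -> str:
        return self.lineage.species


class ReferenceDatabase:
    """Ordered, ID-unique collection of :class:`ReferenceRecord`."""

    def __init__(
        self,
        records: Iterable[ReferenceRecord],
        label: str = "",
        scope: str = "world",
        region: str = "general",
    ):
        self.records: list[ReferenceRecord] = list(records)
        self.label = label
        self.scope = scope
        self.region = region
        self._by_id = {r.seq_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            seen: set[str] = set()
            dup = [r.seq_id for r in self.records if r.seq_id in seen or seen.add(r.seq_id)]
            raise ValueError(f"duplicate seq_id(s): {sorted(set(dup))[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __getitem__(self, seq_id: str) -> ReferenceRecord:
        return self._by_id[seq_id]

    def taxmap(self) -> dict[str, TaxonLineage]:
        """subject_id → lineage map used by the assignment methods."""
        return {r.seq_id: r.lineage for r in self.records}

    def subset(self, seq_ids: Iterable[str], **kwargs) -> "ReferenceDatabase":
        """New database keeping *seq_ids* (load order preserved)."""
        wanted = set(seq_ids)
        return ReferenceDatabase(
            [r for r in self.records if r.seq_id in wanted],
            label=kwargs.get("label", self.label),
            scope=kwargs.get("scope", self.scope),
            region=kwargs.get("region", self.region),
        )

    def species_set(self) -> set[str]:
        return {r.species for r in self.records}


# ---------------------------------------------------------------------------
# I/O

def read_taxonomy_table(path: str | Path) -> dict[str, TaxonLineage]:
    """Read a 2-column TSV (ID, lineage string); header row optional."""
    taxa: dict[str, TaxonLineage] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected 2 tab-separated columns")
            key, lineage = parts[0].strip(), parts[1]
            if i == 0 and (key.startswith("#") or key.lower() in ("feature id", "feature-id", "id", "seq_id", "otu id")):
                continue
            taxa[key] = parse_lineage(lineage)
    return taxa


def read_reference(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    label: str = "",
    origin: str = FOREIGN,
) -> ReferenceDatabase:
    """Join a FASTA file with its taxonomy table into a database.

    FASTA entries without a taxonomy row are dropped (count logged).
    Genus/species binomial mismatches are reported as warnings, never
    repaired.
    """
    taxa = read_taxonomy_table(taxonomy_path)
    records: list[ReferenceRecord] = []
    n_missing = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        lineage = taxa.get(rec.id)
        if lineage is None:
            n_missing += 1
            continue
        if not lineage.is_consistent_binomial():
            logger.warning(
                "%s: species %r does not start with genus %r",
                rec.id, lineage.species, lineage.genus,
            )
        records.append(
            ReferenceRecord(rec.id, str(rec.seq), lineage, origin=origin)
        )
    if n_missing:
        logger.warning("%s: dropped %d FASTA entries without taxonomy", fasta_path, n_missing)
    if not records:
        raise ValueError(f"no joinable records between {fasta_path} and {taxonomy_path}")
    return ReferenceDatabase(records, label=label)


def write_reference(
    db: ReferenceDatabase, fasta_path: str | Path, taxonomy_path: str | Path
) -> None:
    """Write FASTA + taxonomy TSV in database order."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in db]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with open(taxonomy_path, "w") as fh:
        for r in db:
            fh.write(f"{r.seq_id}\t{r.lineage.to_string()}\n")


def read_local_species(path: str | Path) -> set[str]:
    """Plain-text list of species binomials, one per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_local_species(species: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(species):
            fh.write(name + "\n")


# ---------------------------------------------------------------------------
# Local/World subsetting and target selection

def label_origin(db: ReferenceDatabase, local_species: set[str]) -> ReferenceDatabase:
    """Flag records whose species is in *local_species* as local."""
    records = [
        replace(r, origin=LOCAL if r.species in local_species else FOREIGN)
        for r in db
    ]
    out = ReferenceDatabase(records, label=db.label, scope=db.scope, region=db.region)
    n_local = sum(r.origin == LOCAL for r in out)
    logger.info("labelled %d local / %d foreign records", n_local, len(out) - n_local)
    return out


def subset_local(db: ReferenceDatabase) -> ReferenceDatabase:
    """Local DB: only records of local species (scope becomes 'local')."""
    records = [r for r in db if r.origin == LOCAL]
    if not records:
        raise ValueError("no local records; label origins before subsetting")
    return ReferenceDatabase(records, label=db.label, scope=LOCAL, region=db.region)


def select_targets(
    db: ReferenceDatabase, foreign_fraction: float = 0.10, seed: int = 0
) -> list[str]:
    """Choose the sequences to cross-validate.

    All local records plus a seeded uniform sample (without replacement)
    of ``round(foreign_fraction * n_foreign)`` foreign records; records
    whose species name is a hybrid or an imprecise identification are
    then excluded.  Deterministic given *seed*; output in load order.
    """
    if not 0 <= foreign_fraction <= 1:
        raise ValueError("foreign_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    foreign_idx = [i for i, r in enumerate(db.records) if r.origin == FOREIGN]
    n_sample = round(foreign_fraction * len(foreign_idx))
    sampled = set(rng.choice(foreign_idx, size=n_sample, replace=False)) if n_sample else set()
    targets = []
    for i, r in enumerate(db.records):
        if r.origin != LOCAL and i not in sampled:
            continue
        if is_hybrid(r.species) or is_imprecise(r.species):
            continue
        targets.append(r.seq_id)
    return targets


# ---------------------------------------------------------------------------
# Amplicon restriction

def _site_mismatches(window: str, primer: str) -> int:
    """Mismatch count with IUPAC degeneracy honoured on the primer side."""
    return sum(
        base not in IUPAC_CODES[p] for base, p in zip(window, primer)
    )


def _best_site(seq: str, primer: str, start: int, tie: str) -> tuple[int, int] | None:
    """Best primer site at or after *start*: fewest mismatches, ties broken
    toward the leftmost (forward) or rightmost (reverse) position."""
    m = len(primer)
    best: tuple[int, int] | None = None
    for pos in range(start, len(seq) - m + 1):
        mm = _site_mismatches(seq[pos : pos + m], primer)
        if best is None or mm < best[1] or (mm == best[1] and tie == "right"):
            best = (pos, mm)
    return best


def extract_amplicon(
    record: ReferenceRecord,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 0,
    include_primers: bool = False,
) -> ReferenceRecord | None:
    """Extract the region a primer pair would amplify, or ``None``.

    The reverse primer is given 5'→3' on the reverse strand and is
    reverse-complemented before matching.  Each site must align with at
    most *max_mismatch* mismatches under IUPAC-aware matching (degeneracy
    honoured on the primer side only).  By default the primers
    themselves are excluded from the product, mimicking insert-only
    restricted reference databases.  Absence of either site — the
    full-length sequence only partially overlapping the target region,
    or a primer site with too many SNPs — yields ``None``.
    """
    seq = record.sequence
    fwd = fwd_primer.upper()
    rev_rc = reverse_complement(rev_primer)
    hit_f = _best_site(seq, fwd, 0, tie="left")
    if hit_f is None or hit_f[1] > max_mismatch:
        return None
    f_start, _ = hit_f
    f_end = f_start + len(fwd)
    hit_r = _best_site(seq, rev_rc, f_end, tie="right")
    if hit_r is None or hit_r[1] > max_mismatch:
        return None
    r_start, _ = hit_r
    if include_primers:
        amplicon = seq[f_start : r_start + len(rev_rc)]
    else:
        amplicon = seq[f_end:r_start]
    if not amplicon:
        return None
    return ReferenceRecord(
        record.seq_id,
        amplicon,
        record.lineage,
        origin=record.origin,
        source_accession=record.source_accession,
    )


def restrict_database(
    db: ReferenceDatabase,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 0,
    include_primers: bool = False,
) -> ReferenceDatabase:
    """Amplicon-restricted counterpart of *db* (records failing primer
    matching are dropped, count logged)."""
    records = []
    for r in db:
        out = extract_amplicon(r, fwd_primer, rev_primer, max_mismatch, include_primers)
        if out is not None:
            records.append(out)
    logger.info(
        "restricted %d/%d records (%d lost to primer matching)",
        len(records), len(db), len(db) - len(records),
    )
    return ReferenceDatabase(records, label=db.label, scope=db.scope, region="restricted")
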