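"""Cross-validation engine: leaked and k-fold designs over
General / Restricted / Restricted-General regions and Local / World
database scopes.

Two CV modes test different hypotheses.  *Leaked* CV keeps each
target's own record in the reference, measuring the searcher's ability
to retrieve an exact match among near-identical neighbours.  *k-fold*
CV removes each fold's records before searching, measuring how well
the nearest remaining relative recovers the taxonomy — the more
realistic scenario for metabarcoding reads whose exact sequence is
often absent from the database.  The *restricted-general* design
blasts primer-restricted targets against the full-length database,
purging the full-length parents (by source accession) of each fold's
members first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .assign import EVAL_RANKS, METHOD_NAMES, TopNPlusParams, assign
from .refdb import FOREIGN, ReferenceDatabase, select_targets, subset_local
from .search import HitTable, SearchParams, naive_search

logger = logging.getLogger(__name__)

Backend = Callable[[ReferenceDatabase, ReferenceDatabase], HitTable]

#: Stable output column order of the results table.
RESULT_COLUMNS: list[str] = (
    ["query_id", "fold", "method", "origin"]
    + [f"true_{r}" for r in EVAL_RANKS]
    + [c for r in EVAL_RANKS for c in
       (f"{r}_taxon", f"{r}_identity", f"{r}_consensus", f"{r}_correct")]
)


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation run configuration."""

    cv_mode: str = "kfold"
    k: int = 10
    region_design: str = "general"
    db_scope: str = "world"
    foreign_fraction: float = 0.10
    seed: int = 0
    max_hits: int = 10
    methods: tuple[str, ...] = METHOD_NAMES
    topnplus: TopNPlusParams = field(default_factory=TopNPlusParams)

    def __post_init__(self) -> None:
        if self.cv_mode not in ("leaked", "kfold"):
            raise ValueError("cv_mode must be 'leaked' or 'kfold'")
        if self.cv_mode == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2 for kfold CV")
        if self.region_design not in ("general", "restricted", "restricted_general"):
            raise ValueError(f"bad region_design {self.region_design!r}")
        if self.db_scope not in ("world", "local"):
            raise ValueError(f"bad db_scope {self.db_scope!r}")
        if not 0 <= self.foreign_fraction <= 1:
            raise ValueError("foreign_fraction must be in [0, 1]")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


def make_folds(target_ids: list[str], k: int, seed: int) -> dict[str, int]:
    """Seeded random split into *k* near-equal folds (sizes differ by <= 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(target_ids) < k:
        raise ValueError(f"{len(target_ids)} targets < k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(target_ids))
    folds: dict[str, int] = {}
    for fold_idx, chunk in enumerate(np.array_split(perm, k)):
        for i in chunk:
            folds[target_ids[int(i)]] = fold_idx
    return folds


def build_fold_reference(
    db: ReferenceDatabase,
    fold_ids: set[str],
    cv_mode: str,
    region_design: str = "general",
    restricted_parent_map: Mapping[str, str] | None = None,
) -> ReferenceDatabase:
    """Reference database seen by one fold's queries.

    leaked → the full database; kfold general/restricted → the database
    minus the fold's own records; kfold restricted-general → the
    general database minus every full-length record sharing a source
    accession with a fold member.
    """
    if cv_mode == "leaked":
        return db
    if region_design == "restricted_general":
        if restricted_parent_map is None:
            raise ValueError("restricted_general needs a restricted_parent_map")
        accs = {restricted_parent_map[q] for q in fold_ids if q in restricted_parent_map}
        records = [r for r in db if r.source_accession not in accs]
    else:
        records = [r for r in db if r.seq_id not in fold_ids]
    if not records:
        raise ValueError("fold reference is empty")
    return ReferenceDatabase(records, label=db.label, scope=db.scope, region=db.region)


def run_cv(
    queries_db: ReferenceDatabase,
    reference_db: ReferenceDatabase,
    config: CvConfig,
    backend: Backend | None = None,
) -> pd.DataFrame:
    """Run a full cross-validation and return the per-sequence table.

    Targets are selected from *queries_db* (all local records plus a
    seeded foreign subsample, hybrids/imprecise names excluded), folds
    are drawn over that filtered target set, and for each fold the
    reference is rebuilt, searched, truncated to the top ``max_hits``
    and fed to every configured assignment method.  The result has one
    row per target × method with per-rank predictions, scores and
    correctness flags (unassigned → not correct).  Deterministic given
    config, seed and backend.
    """
    if backend is None:
        params = SearchParams(max_hits=config.max_hits)
        backend = lambda q, r: naive_search(q, r, params)  # noqa: E731

    targets = select_targets(queries_db, config.foreign_fraction, config.seed)
    if not targets:
        raise ValueError("no targets selected")

    reference = reference_db
    if config.db_scope == "local":
        reference = subset_local(reference_db)
        foreign_targets = sum(queries_db[t].origin == FOREIGN for t in targets)
        if config.cv_mode == "leaked" and foreign_targets:
            warnings.warn(
                "leaked CV against a Local DB: foreign targets are absent from "
                "the reference, so their design degenerates to k-fold-like CV",
                stacklevel=2,
            )

    if config.cv_mode == "leaked":
        fold_of = {t: 0 for t in targets}
        n_folds = 1
    else:
        fold_of = make_folds(targets, config.k, config.seed)
        n_folds = config.k

    parent_map = (
        {r.seq_id: r.source_accession for r in queries_db}
        if config.region_design == "restricted_general"
        else None
    )

    rows: list[dict] = []
    for fold_idx in range(n_folds):
        fold_ids = {t for t, f in fold_of.items() if f == fold_idx}
        if not fold_ids:
            continue
        fold_ref = build_fold_reference(
            reference, fold_ids, config.cv_mode, config.region_design, parent_map
        )
        fold_queries = queries_db.subset(fold_ids)
        try:
            table = backend(fold_queries, fold_ref).truncated(config.max_hits)
        except Exception as exc:
            raise RuntimeError(
                f"search backend failed on fold {fold_idx} "
                f"({len(fold_queries)} queries)"
            ) from exc
        taxmap = fold_ref.taxmap()
        logger.info("fold %d: %d queries vs %d references", fold_idx,
                    len(fold_queries), len(fold_ref))
        for rec in fold_queries:
            hits = table.hits(rec.seq_id)
            for method in config.methods:
                res = assign(method, rec.seq_id, hits, taxmap, config.topnplus)
                row: dict = {
                    "query_id": rec.seq_id,
                    "fold": fold_idx,
                    "method": method,
                    "origin": rec.origin,
                }
                for rank in EVAL_RANKS:
                    ra = res.at(rank)
                    true = rec.lineage.taxon_at(rank)
                    row[f"true_{rank}"] = true
                    row[f"{rank}_taxon"] = ra.taxon
                    row[f"{rank}_identity"] = ra.identity
                    row[f"{rank}_consensus"] = ra.consensus
                    row[f"{rank}_correct"] = bool(ra.assigned and ra.taxon == true)
                rows.append(row)

    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.sort_values(["fold", "query_id", "method"], kind="stable").reset_index(drop=True)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated results with "NA" for unassigned ranks."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for rank in EVAL_RANKS:
        col = f"{rank}_correct"
        if col in df:
            df[col] = df[col].astype(bool)
    return df
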