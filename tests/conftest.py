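"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from barcodecv.search import HitRecord, canonical_sort
from barcodecv.taxonomy import UNKNOWN, TaxonLineage


def make_lineage(family="Brassicaceae", genus="Brassica", species="Brassica nigra"):
    return TaxonLineage(
        ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Brassicales",
         family, genus, species)
    )


def brassica_hits():
    """The worked 10-hit table: 2x Brassica napus, 6x Brassica nigra,
    2x Sinapis alba, with a taxonomy map for the subjects."""
    taxmap = {}
    hits = []
    plan = (
        [("Brassica", "Brassica napus")] * 2
        + [("Brassica", "Brassica nigra")] * 6
        + [("Sinapis", "Sinapis alba")] * 2
    )
    for i, (genus, species) in enumerate(plan):
        sid = f"s{i}"
        taxmap[sid] = make_lineage("Brassicaceae", genus, species)
        hits.append(
            HitRecord("q", sid, 99.0, 350, 1e-60, 120.0 - i, i + 1)
        )
    return hits, taxmap


def random_hit_table(rng: np.random.Generator, allow_unknown: bool = False):
    """A random query's hit list plus taxonomy map, exercising ties,
    variable lengths/E-values and (optionally) rank-unknown lineages."""
    n = int(rng.integers(1, 11))
    n_species = int(rng.integers(1, 5))
    species_pool = []
    for s in range(n_species):
        fam = f"Fam{rng.integers(1, 3)}"
        gen = f"{fam}_Gen{rng.integers(1, 3)}"
        species_pool.append((fam, gen, f"{gen} sp{s}"))
    hits, taxmap = [], {}
    # draw bitscores from a small grid so exact ties are frequent
    scores = rng.choice([50.0, 80.0, 80.0, 100.0, 120.0], size=n)
    for i in range(n):
        fam, gen, sp = species_pool[int(rng.integers(0, n_species))]
        if allow_unknown and rng.random() < 0.15:
            sp = UNKNOWN
        if allow_unknown and rng.random() < 0.05:
            gen = UNKNOWN
        sid = f"s{i}"
        taxmap[sid] = TaxonLineage(
            ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Ord",
             fam, gen, sp)
        )
        hits.append(
            HitRecord(
                query_id="q",
                subject_id=sid,
                pident=float(np.round(rng.uniform(80, 100), 2)),
                align_length=int(rng.integers(40, 500)),
                evalue=float(10.0 ** rng.uniform(-80, -5)),
                bitscore=float(scores[i]),
                input_rank=i + 1,
            )
        )
    return canonical_sort(hits), taxmap


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)
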