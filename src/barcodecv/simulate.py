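"""Synthetic reference databases with controlled taxonomic structure.

The generator emulates, at desk scale, a curated barcode reference
database: a hierarchy of families → genera → species, several records
per species, and a local/foreign species split.  Sequences evolve down
a star tree at each level under an i.i.d. substitution model: every
site mutates independently with the level's divergence probability, to
one of the three other bases (Jukes–Cantor-like, no indels by
default).  The expected Hamming distance between two records therefore
grows with the summed divergences along their connecting path, which
is what makes rank-structured similarity — and hence every
cross-validation contrast — testable without downloads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .refdb import (
    ReferenceDatabase,
    ReferenceRecord,
    label_origin,
    reverse_complement,
    write_local_species,
    write_reference,
)
from .taxonomy import TaxonLineage

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Shape and divergence parameters of a simulated database.

    Divergences are expected per-site substitution proportions applied
    on the path root → family → genus → species → record; a
    "well-separated" database needs d_within < d_species < d_genus <=
    d_family.  ``records_per_species`` may be an int or an inclusive
    (lo, hi) range sampled per species.  With primers set, each
    sequence is built as flank + forward primer + core + revcomp
    (reverse primer) + flank so that amplicon restriction is exercised.
    """

    n_families: int = 3
    genera_per_family: int = 2
    species_per_genus: int = 3
    records_per_species: int | tuple[int, int] = 3
    sequence_length: int = 300
    d_family: float = 0.20
    d_genus: float = 0.10
    d_species: float = 0.05
    d_within: float = 0.005
    fraction_local: float = 0.5
    fraction_hybrid: float = 0.0
    fraction_imprecise: float = 0.0
    fwd_primer: str | None = None
    rev_primer: str | None = None
    flank_length: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_family", "d_genus", "d_species", "d_within"):
            d = getattr(self, name)
            if not 0.0 <= d <= 0.75:
                raise ValueError(f"{name}={d} outside [0, 0.75]")
        for name in ("fraction_local", "fraction_hybrid", "fraction_imprecise"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")


def _mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability *d* to one of the other 3 bases."""
    out = seq.copy()
    sites = np.nonzero(rng.random(seq.size) < d)[0]
    if sites.size:
        # shift by 1..3 positions in base space: never the same base
        out[sites] = (out[sites] + rng.integers(1, 4, size=sites.size)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def simulate_database(config: SimConfig) -> tuple[ReferenceDatabase, list[str]]:
    """Generate a reference database and its local-species list.

    Fully deterministic given ``config.seed`` (byte-identical FASTA/TSV
    when written).  Names are systematic: family "Fam01", genus
    "Gen01_2", species "Gen01_2 species3".  A configured fraction of
    species receives hybrid ("×") or open-nomenclature ("sp.") name
    forms so that target filtering can be exercised.
    """
    rng = np.random.default_rng(config.seed)
    root = rng.integers(0, 4, size=config.sequence_length, dtype=np.int64)

    species_entries: list[tuple[TaxonLineage, np.ndarray]] = []
    for fi in range(1, config.n_families + 1):
        fam_seq = _mutate(root, config.d_family, rng)
        fam = f"Fam{fi:02d}"
        order = f"Ord{fi:02d}"
        for gi in range(1, config.genera_per_family + 1):
            gen_seq = _mutate(fam_seq, config.d_genus, rng)
            genus = f"Gen{fi:02d}_{gi}"
            for si in range(1, config.species_per_genus + 1):
                sp_seq = _mutate(gen_seq, config.d_species, rng)
                species = f"{genus} species{si}"
                lineage = TaxonLineage(
                    ("Viridiplantae", "Streptophyta", "Magnoliopsida",
                     order, fam, genus, species)
                )
                species_entries.append((lineage, sp_seq))

    n_species = len(species_entries)
    perm = rng.permutation(n_species)
    n_local = round(config.fraction_local * n_species)
    local_idx = set(perm[:n_local].tolist())
    n_hybrid = round(config.fraction_hybrid * n_species)
    n_imprec = round(config.fraction_imprecise * n_species)
    hybrid_idx = set(perm[n_local:][:n_hybrid].tolist()) if n_hybrid else set()
    imprec_idx = (
        set(perm[n_local + n_hybrid:][:n_imprec].tolist()) if n_imprec else set()
    )

    records: list[ReferenceRecord] = []
    local_species: list[str] = []
    counter = 0
    for idx, (lineage, sp_seq) in enumerate(species_entries):
        names = list(lineage.names)
        genus = names[5]
        if idx in hybrid_idx:
            epithet = names[6].split()[1]
            names[6] = f"{genus} × {epithet}"
        elif idx in imprec_idx:
            names[6] = f"{genus} sp."
        lineage = TaxonLineage(tuple(names))
        if idx in local_idx:
            local_species.append(names[6])
        if isinstance(config.records_per_species, tuple):
            lo, hi = config.records_per_species
            n_rec = int(rng.integers(lo, hi + 1))
        else:
            n_rec = config.records_per_species
        for _ in range(n_rec):
            counter += 1
            rec_seq = _to_str(_mutate(sp_seq, config.d_within, rng))
            if config.fwd_primer:
                core = rec_seq
                left = _to_str(rng.integers(0, 4, size=config.flank_length))
                right = _to_str(rng.integers(0, 4, size=config.flank_length))
                rec_seq = (
                    left + config.fwd_primer + core
                    + reverse_complement(config.rev_primer) + right
                )
            records.append(
                ReferenceRecord(f"S{counter:05d}", rec_seq, lineage)
            )

    db = label_origin(ReferenceDatabase(records, label="simulated"), set(local_species))
    return db, sorted(local_species)


def write_simulated(
    db: ReferenceDatabase,
    local_species: list[str],
    config: SimConfig,
    outdir: str | Path,
) -> None:
    """Write FASTA + taxonomy TSV + local-species list + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reference(db, outdir / "reference.fasta", outdir / "taxonomy.tsv")
    write_local_species(local_species, outdir / "local_species.txt")
    manifest = asdict(config)
    manifest["n_records"] = len(db)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)


@dataclass(frozen=True)
class Benchmark:
    """A named preset database with its expected qualitative outcome."""

    name: str
    config: SimConfig
    db: ReferenceDatabase
    local_species: list[str]
    expectation: str


#: Preset configurations reproducing the qualitative contrasts the
#: cross-validation designs are meant to expose.
PRESETS: Mapping[str, tuple[SimConfig, str]] = {
    "well-separated": (
        SimConfig(d_family=0.20, d_genus=0.10, d_species=0.05, d_within=0.002,
                  records_per_species=3, fraction_local=0.6),
        "10-fold species accuracy high; leaked CV accuracy >= 10-fold",
    ),
    "singleton-species": (
        SimConfig(d_family=0.20, d_genus=0.10, d_species=0.05, d_within=0.002,
                  records_per_species=1, fraction_local=0.6),
        "10-fold species accuracy 0 (true label absent once removed); genus > 0",
    ),
    "low-interspecific-divergence": (
        SimConfig(d_family=0.20, d_genus=0.10, d_species=0.0, d_within=0.0,
                  records_per_species=(1, 4), fraction_local=0.6, seed=1),
        "frequent best-bit-score ties, so TopHitPlus can beat TopHit",
    ),
    "foreign-vs-local": (
        SimConfig(d_family=0.20, d_genus=0.10, d_species=0.05, d_within=0.002,
                  records_per_species=3, fraction_local=0.5),
        "Local DB lacks foreign species: foreign species accuracy 0 on Local DB",
    ),
}


def make_benchmark_suite(
    presets: list[str] | None = None, seed: int | None = None
) -> dict[str, Benchmark]:
    """Build the named preset databases (optionally overriding the seed)."""
    out: dict[str, Benchmark] = {}
    for name in presets or list(PRESETS):
        config, expectation = PRESETS[name]
        if seed is not None:
            config = replace(config, seed=seed)
        db, local = simulate_database(config)
        out[name] = Benchmark(name, config, db, local, expectation)
    return out
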