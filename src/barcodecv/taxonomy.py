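"""Ranked taxonomic lineages and species-name quality checks.

A lineage is a fixed, ordered set of seven Linnaean ranks
(kingdom ... species).  Missing levels are stored explicitly as
``"unknown"`` so that every lineage has exactly seven slots and rank
comparisons are always well defined.  Lineage strings follow the
QIIME2 feature-taxonomy dialect: semicolon-delimited fields, optional
``x__`` rank prefixes, optional surrounding whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

UNKNOWN = "unknown"

#: Epithet-position tokens marking an identification not resolved to species.
IMPRECISE_TOKENS = frozenset({"sp", "sp.", "spp", "spp.", "cf", "cf.", "aff", "aff."})

#: Tokens marking a hybrid taxon (besides the multiplication sign).
HYBRID_TOKENS = frozenset({"x", "hybrid"})

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")
_WS_RE = re.compile(r"\s+")


class LineageFormatError(ValueError):
    """Raised when a lineage string cannot be interpreted."""


@dataclass(frozen=True)
class TaxonLineage:
    """Seven-rank taxonomic lineage with explicit ``unknown`` placeholders."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise LineageFormatError(
                f"lineage must have exactly {len(RANKS)} ranks, got {len(self.names)}"
            )

    def taxon_at(self, rank: str) -> str:
        """Return the taxon name stored at *rank* (one of :data:`RANKS`)."""
        try:
            return self.names[RANKS.index(rank)]
        except ValueError:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}") from None

    @property
    def family(self) -> str:
        return self.names[4]

    @property
    def genus(self) -> str:
        return self.names[5]

    @property
    def species(self) -> str:
        return self.names[6]

    def to_string(self, delimiter: str = ";") -> str:
        """Serialize back to a delimited lineage string (no rank prefixes)."""
        return delimiter.join(self.names)

    def is_consistent_binomial(self) -> bool:
        """True unless genus and species are both known and disagree.

        The species binomial's first token must equal the genus name
        whenever both are known; violations are surfaced by loaders as
        warnings, never silently repaired.
        """
        if self.genus == UNKNOWN or self.species == UNKNOWN:
            return True
        return self.species.split()[0] == self.genus


def _clean_field(field: str) -> str:
    field = _PREFIX_RE.sub("", field.strip())
    field = _WS_RE.sub(" ", field)
    return field if field else UNKNOWN


def parse_lineage(lineage_string: str, delimiter: str = ";") -> TaxonLineage:
    """Parse a delimited lineage string into a :class:`TaxonLineage`.

    Short strings are right-padded with ``"unknown"``; empty fields map
    to ``"unknown"``; ``x__`` style rank prefixes are stripped.  More
    than seven fields is a format error.
    """
    fields = lineage_string.split(delimiter) if lineage_string.strip() else []
    if len(fields) > len(RANKS):
        raise LineageFormatError(
            f"lineage has {len(fields)} fields, at most {len(RANKS)} allowed: "
            f"{lineage_string!r}"
        )
    names = [_clean_field(f) for f in fields]
    names.extend([UNKNOWN] * (len(RANKS) - len(names)))
    return TaxonLineage(tuple(names))


def taxon_at(lineage: TaxonLineage, rank: str) -> str:
    """Functional alias for :meth:`TaxonLineage.taxon_at`."""
    return lineage.taxon_at(rank)


def is_hybrid(species_name: str, hybrid_tokens: frozenset[str] = HYBRID_TOKENS) -> bool:
    """True if the name denotes a hybrid taxon.

    Detects the multiplication sign "×", a standalone token "x" between
    two name tokens, or the token "hybrid" (case-insensitive).
    """
    if "×" in species_name:
        return True
    tokens = species_name.split()
    low = [t.lower() for t in tokens]
    if "hybrid" in low and "hybrid" in hybrid_tokens:
        return True
    if "x" in hybrid_tokens:
        for i, tok in enumerate(low):
            if tok == "x" and 0 < i < len(tokens) - 1:
                return True
    return False


def is_imprecise(
    species_name: str, imprecise_tokens: frozenset[str] = IMPRECISE_TOKENS
) -> bool:
    """True if the name is not a resolved species-level identification.

    A name is imprecise when it is ``"unknown"``, a single token (no
    epithet), or carries an open-nomenclature token (``sp.``, ``cf.``,
    ``aff.``, ``spp.`` ...) in the epithet position.
    """
    name = _WS_RE.sub(" ", species_name.strip())
    if not name or name.lower() == UNKNOWN:
        return True
    tokens = name.split()
    if len(tokens) < 2:
        return True
    return any(tok.lower() in imprecise_tokens for tok in tokens[1:])
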