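"""Domain records: chemical profiles, leaf samples, feeding records.

Units convention, used everywhere without repetition: masses in g dry
weight, concentrations in mg per g dry weight, absolute chemical amounts
(ingested/excreted) in mg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .catalog import ACTIVITY_IDS, CompoundCatalog


class ValidationError(ValueError):
    """A record violates a schema invariant (negative mass, bad id, ...)."""


@dataclass
class ChemProfile:
    """Concentrations of catalog compounds plus the two activity measures.

    ``concentrations`` maps compound id -> mg/g dry weight.  A compound
    missing from the mapping means "not detected" and reads as 0.0 — distinct
    from a malformed table cell, which the readers reject.
    """

    concentrations: dict[str, float]
    oxidative_activity: float = 0.0
    protein_precipitation: float = 0.0

    def __post_init__(self) -> None:
        for cid, v in self.concentrations.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"concentration of {cid!r} must be finite and >= 0, got {v!r}"
                )
        for label, v in zip(ACTIVITY_IDS, (self.oxidative_activity, self.protein_precipitation)):
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"activity {label} must be finite and >= 0, got {v!r}")

    def value(self, variable: str) -> float:
        """Concentration of a compound, or an activity by its column name."""
        if variable == "Ox":
            return self.oxidative_activity
        if variable == "PP":
            return self.protein_precipitation
        return self.concentrations.get(variable, 0.0)

    def variables(self, catalog: CompoundCatalog) -> list[str]:
        """All analysis variables in catalog order: compounds then activities."""
        return catalog.ids + list(ACTIVITY_IDS)


@dataclass
class LeafSample:
    """One tree's leaf chemistry (pooled leaves, one analytical profile)."""

    species: str
    tree: str
    profile: ChemProfile
    is_feeding_tree: bool = False


@dataclass
class SpeciesConstants:
    """Per-species fresh:dry leaf mass ratio used to convert offered leaf mass."""

    species: str
    fresh_to_dry: float

    def __post_init__(self) -> None:
        if not self.fresh_to_dry > 1:
            raise ValidationError(
                f"fresh_to_dry for {self.species!r} must exceed 1, got {self.fresh_to_dry}"
            )


@dataclass
class FeedingRecord:
    """One caterpillar in one experimental phase.

    ``w_leaf`` (dry leaf mass eaten) is computed eagerly by the readers and
    generator from ``fresh_offered / fresh_to_dry - dry_remaining``.  Records
    with ``w_leaf <= 0`` are flagged ``excluded`` — non-feeders are kept in
    the tables for bookkeeping but no analysis may use them.
    """

    caterpillar: str
    phase: int
    phase1_host: str
    phase2_host: str | None
    fresh_offered: float
    dry_remaining: float
    frass_dry: float
    frass_profile: ChemProfile | None = None
    leaf_profile: ChemProfile | None = None
    w_leaf: float = 0.0
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.phase not in (1, 2):
            raise ValidationError(f"phase must be 1 or 2, got {self.phase}")
        if self.phase == 2 and not self.phase2_host:
            raise ValidationError(f"phase-2 record {self.caterpillar!r} lacks phase2_host")
        for name in ("fresh_offered", "dry_remaining", "frass_dry"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{name} of {self.caterpillar!r} must be finite and >= 0, got {v!r}"
                )

    @property
    def current_host(self) -> str:
        """Species the caterpillar is feeding on in this record's phase."""
        return self.phase2_host if self.phase == 2 else self.phase1_host  # type: ignore[return-value]

    @property
    def w_frass(self) -> float:
        """Dry frass mass in g (alias of ``frass_dry`` in the W·C notation)."""
        return self.frass_dry

    @property
    def retained(self) -> float:
        """Retained leaf biomass: dry mass eaten minus dry frass produced (g)."""
        return self.w_leaf - self.frass_dry

    @property
    def is_one_host(self) -> bool:
        """True for phase-2 caterpillars kept on their original host."""
        return self.phase == 2 and self.phase2_host == self.phase1_host


def active_records(records: list[FeedingRecord]) -> list[FeedingRecord]:
    """Records not flagged excluded — the only ones analyses may consume."""
    return [r for r in records if not r.excluded]


@dataclass
class Experiment:
    """A complete two-phase feeding experiment in memory."""

    catalog: CompoundCatalog
    leaves: list[LeafSample]
    records: list[FeedingRecord]
    constants: dict[str, SpeciesConstants] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for leaf in self.leaves:
            seen.setdefault(leaf.species, None)
        return list(seen)

    def feeding_tree_profile(self, species: str) -> ChemProfile:
        for leaf in self.leaves:
            if leaf.species == species and leaf.is_feeding_tree:
                return leaf.profile
        raise KeyError(f"no feeding tree designated for species {species!r}")

    def phase_records(self, phase: int, *, include_excluded: bool = False) -> list[FeedingRecord]:
        out = [r for r in self.records if r.phase == phase]
        if not include_excluded:
            out = active_records(out)
        return out
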