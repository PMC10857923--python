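"""Compound catalog: identities, subgroups and isomer families of polyphenols.

A catalog names the chemical variables of an experiment.  Each compound
belongs to one of four polyphenol subgroups (cinnamic acid derivatives,
flavonoids, hydrolyzable tannins, proanthocyanidins).  Compounds that
interconvert in the alkaline insect gut — e.g. the three caffeoylquinic
acid positional isomers — share an ``isomer_family`` key, which is what the
gut-pH module operates on.

Two assay-derived activity measures (oxidative activity ``Ox`` and protein
precipitation capacity ``PP``, both in mg/g standard equivalents) travel
with every profile but are never part of a catalog: they are functional
summaries of the mixture, not compounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

SUBGROUPS: tuple[str, ...] = (
    "cinnamic_acid_derivative",
    "flavonoid",
    "hydrolyzable_tannin",
    "proanthocyanidin",
)

#: column names of the two activity measures, kept alongside compounds in
#: every profile table
ACTIVITY_IDS: tuple[str, str] = ("Ox", "PP")

#: conventional subgroup-total column names (used by the subgroup basis)
SUBGROUP_TOTAL_IDS: dict[str, str] = {
    "cinnamic_acid_derivative": "CAs",
    "flavonoid": "FLs",
    "hydrolyzable_tannin": "HHs",
    "proanthocyanidin": "PCs",
}


@dataclass(frozen=True)
class Compound:
    """One quantified polyphenol.

    ``id`` is the short analytical code (e.g. ``"CA1"``); ``subgroup`` must be
    one of :data:`SUBGROUPS`; ``isomer_family`` groups interconvertible
    isomers and is ``None`` for compounds without such a family.
    """

    id: str
    name: str
    subgroup: str
    isomer_family: str | None = None

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise ValueError(
                f"unknown subgroup {self.subgroup!r} for compound {self.id!r}; "
                f"expected one of {SUBGROUPS}"
            )
        if self.id in ACTIVITY_IDS:
            raise ValueError(f"compound id {self.id!r} collides with an activity column")


@dataclass
class CompoundCatalog:
    """Ordered, unique-id collection of :class:`Compound`."""

    compounds: list[Compound] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids in catalog: {dupes}")
        self._by_id = {c.id: c for c in self.compounds}

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def __getitem__(self, compound_id: str) -> Compound:
        return self._by_id[compound_id]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def subgroup_members(self, subgroup: str) -> list[str]:
        if subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {subgroup!r}")
        return [c.id for c in self.compounds if c.subgroup == subgroup]

    def family_members(self, family: str) -> list[str]:
        """Compound ids of one isomer family, in catalog order."""
        members = [c.id for c in self.compounds if c.isomer_family == family]
        if not members:
            raise KeyError(f"no compounds with isomer_family {family!r}")
        return members

    @property
    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for c in self.compounds:
            if c.isomer_family is not None:
                out.setdefault(c.isomer_family, []).append(c.id)
        return out

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "id": c.id,
                "name": c.name,
                "subgroup": c.subgroup,
                "isomer_family": c.isomer_family,
            }
            for c in self.compounds
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CompoundCatalog":
        payload = json.loads(Path(path).read_text())
        return cls([Compound(**entry) for entry in payload])

    @classmethod
    def from_compounds(cls, compounds: Iterable[Compound]) -> "CompoundCatalog":
        return cls(list(compounds))


def default_catalog() -> CompoundCatalog:
    """The 25-compound catalog of the default synthetic experiment.

    Six cinnamic acid derivatives (the first three being the interconvertible
    caffeoylquinic acid isomers), six hydrolyzable tannins, nine flavonoid
    glycosides and four proanthocyanidin-type compounds.
    """
    cqa = "caffeoyl_quinic_acid"
    entries = [
        ("CA1", "3-O-caffeoylquinic acid", "cinnamic_acid_derivative", cqa),
        ("CA2", "4-O-caffeoylquinic acid", "cinnamic_acid_derivative", cqa),
        ("CA3", "5-O-caffeoylquinic acid", "cinnamic_acid_derivative", cqa),
        ("CA4", "3-O-coumaroylquinic acid", "cinnamic_acid_derivative", None),
        ("CA5", "5-O-coumaroylquinic acid", "cinnamic_acid_derivative", None),
        ("CA6", "caffeic acid hexoside", "cinnamic_acid_derivative", None),
        ("HH1", "geraniin", "hydrolyzable_tannin", None),
        ("HH2", "vescalagin", "hydrolyzable_tannin", None),
        ("HH3", "castalagin", "hydrolyzable_tannin", None),
        ("HH4", "vescavaloninic acid", "hydrolyzable_tannin", None),
        ("HH5", "cocciferin D2", "hydrolyzable_tannin", None),
        ("HH6", "1-O-galloylglucose", "hydrolyzable_tannin", None),
        ("FL1", "apigenin 7-O-glucoside", "flavonoid", None),
        ("FL2", "apigenin 7-O-rutinoside", "flavonoid", None),
        ("FL3", "apigenin C-hexoside", "flavonoid", None),
        ("FL4", "kaempferol 3-O-glucoside", "flavonoid", None),
        ("FL5", "quercetin 3-O-glucoside", "flavonoid", None),
        ("FL6", "quercetin 3-O-galactoside", "flavonoid", None),
        ("FL7", "quercetin 3-O-rhamnoside", "flavonoid", None),
        ("FL8", "myricetin 3-O-glucoside", "flavonoid", None),
        ("FL9", "luteolin 7-O-glucoside", "flavonoid", None),
        ("PC1", "catechin", "proanthocyanidin", None),
        ("PC2", "epicatechin", "proanthocyanidin", None),
        ("PC3", "procyanidin B1", "proanthocyanidin", None),
        ("PC4", "procyanidin B2", "proanthocyanidin", None),
    ]
    return CompoundCatalog([Compound(*e) for e in entries])
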