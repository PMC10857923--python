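"""CSV/JSON readers and writers for leaf, frass, feeding and species tables.

File dialect: UTF-8 CSV, one row per sample, compounds as columns, the two
activity columns ``Ox`` and ``PP`` last.  A long-format profile reader
(sample, compound, value) is also provided since archived datasets come in
either layout.

Schemas
-------
leaves.csv   : species, tree, is_feeding_tree, <compound ids...>, Ox, PP
frass.csv    : caterpillar, phase, <compound ids...>, Ox, PP
feeding.csv  : caterpillar, phase, phase1_host, phase2_host,
               fresh_offered, dry_remaining, frass_dry
species.csv  : species, fresh_to_dry
catalog.json : list of {id, name, subgroup, isomer_family}

Missing-value policy: an empty/NaN cell is an error by default
(``missing="reject"``); ``missing="zero"`` imputes 0, the "not detected"
reading.  A compound column absent from a frass table altogether reads as
concentration 0 for every row, which is a different, always-legal situation.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Literal

import pandas as pd

from .catalog import ACTIVITY_IDS, CompoundCatalog
from .mass_balance import consumed_dry
from .types import (
    ChemProfile,
    FeedingRecord,
    LeafSample,
    SpeciesConstants,
    ValidationError,
)

logger = logging.getLogger(__name__)

LEAF_META = ["species", "tree", "is_feeding_tree"]
FRASS_META = ["caterpillar", "phase"]
FEEDING_COLS = [
    "caterpillar",
    "phase",
    "phase1_host",
    "phase2_host",
    "fresh_offered",
    "dry_remaining",
    "frass_dry",
]


class ParseError(ValueError):
    """A table cell could not be interpreted; message names row and column."""


def _cell_float(df: pd.DataFrame, idx, col: str, missing: str) -> float:
    raw = df.at[idx, col]
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        if missing == "zero":
            return 0.0
        raise ParseError(f"missing value at row {idx}, column {col!r}")
    try:
        value = float(raw)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"malformed numeric cell at row {idx}, column {col!r}: {raw!r}") from exc
    if value < 0:
        raise ValidationError(f"negative concentration at row {idx}, column {col!r}: {value}")
    return value


def _profile_from_row(
    df: pd.DataFrame, idx, compound_cols: list[str], missing: str
) -> ChemProfile:
    conc = {c: _cell_float(df, idx, c, missing) for c in compound_cols}
    ox = _cell_float(df, idx, "Ox", missing) if "Ox" in df.columns else 0.0
    pp = _cell_float(df, idx, "PP", missing) if "PP" in df.columns else 0.0
    return ChemProfile(concentrations=conc, oxidative_activity=ox, protein_precipitation=pp)


def _split_columns(
    df: pd.DataFrame, meta: list[str], catalog: CompoundCatalog | None
) -> tuple[list[str], list[str]]:
    """Partition columns into compound columns and unknown extras."""
    rest = [c for c in df.columns if c not in meta and c not in ACTIVITY_IDS]
    if catalog is None:
        return rest, []
    compound_cols = [c for c in rest if c in catalog]
    unknown = [c for c in rest if c not in catalog]
    return compound_cols, unknown


def read_profiles(
    path: str | Path,
    role: Literal["leaf", "frass"],
    catalog: CompoundCatalog | None = None,
    *,
    missing: Literal["reject", "zero"] = "reject",
):
    """Read a wide-format profile table.

    Returns a list of :class:`LeafSample` for ``role="leaf"``, or a dict
    ``(caterpillar, phase) -> ChemProfile`` for ``role="frass"``.  Unknown
    columns (not in the catalog, not metadata) are reported via warning and
    ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=object)
    meta = LEAF_META if role == "leaf" else FRASS_META
    for col in meta:
        if col not in df.columns:
            raise ParseError(f"{path.name}: required column {col!r} absent")
    compound_cols, unknown = _split_columns(df, meta, catalog)
    if unknown:
        logger.warning("%s: ignoring %d unknown columns: %s", path.name, len(unknown), unknown)
    if df.empty:
        logger.warning("%s: empty table", path.name)
        return [] if role == "leaf" else {}

    if role == "leaf":
        samples = []
        for idx in df.index:
            profile = _profile_from_row(df, idx, compound_cols, missing)
            samples.append(
                LeafSample(
                    species=str(df.at[idx, "species"]),
                    tree=str(df.at[idx, "tree"]),
                    is_feeding_tree=str(df.at[idx, "is_feeding_tree"]).lower()
                    in ("1", "true", "yes"),
                    profile=profile,
                )
            )
        return samples

    profiles: dict[tuple[str, int], ChemProfile] = {}
    for idx in df.index:
        key = (str(df.at[idx, "caterpillar"]), int(df.at[idx, "phase"]))
        profiles[key] = _profile_from_row(df, idx, compound_cols, missing)
    return profiles


def read_profiles_long(
    path: str | Path,
    role: Literal["leaf", "frass"],
    catalog: CompoundCatalog | None = None,
    *,
    missing: Literal["reject", "zero"] = "reject",
):
    """Read a long-format table (one row per sample x variable) by pivoting.

    Expected columns: the role's metadata columns plus ``variable`` and
    ``value``; activities appear as variables ``Ox`` and ``PP``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=object)
    meta = LEAF_META if role == "leaf" else FRASS_META
    needed = meta + ["variable", "value"]
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"{path.name}: required column {col!r} absent")
    wide = df.pivot_table(
        index=meta, columns="variable", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    tmp = path.with_suffix(".wide.tmp.csv")
    try:
        wide.to_csv(tmp, index=False)
        return read_profiles(tmp, role, catalog, missing=missing)
    finally:
        tmp.unlink(missing_ok=True)


def write_profiles(samples, path: str | Path, catalog: CompoundCatalog) -> None:
    """Write leaf samples (list) or frass profiles (dict) in the wide dialect."""
    path = Path(path)
    rows = []
    if isinstance(samples, dict):
        for (cat_id, phase), profile in samples.items():
            row = {"caterpillar": cat_id, "phase": phase}
            row.update({cid: profile.value(cid) for cid in catalog.ids})
            row["Ox"] = profile.oxidative_activity
            row["PP"] = profile.protein_precipitation
            rows.append(row)
    else:
        for s in samples:
            row = {
                "species": s.species,
                "tree": s.tree,
                "is_feeding_tree": int(s.is_feeding_tree),
            }
            row.update({cid: s.profile.value(cid) for cid in catalog.ids})
            row["Ox"] = s.profile.oxidative_activity
            row["PP"] = s.profile.protein_precipitation
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_species_constants(path: str | Path) -> dict[str, SpeciesConstants]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        sc = SpeciesConstants(species=str(row["species"]), fresh_to_dry=float(row["fresh_to_dry"]))
        out[sc.species] = sc
    return out


def write_species_constants(constants: dict[str, SpeciesConstants], path: str | Path) -> None:
    pd.DataFrame(
        [{"species": sc.species, "fresh_to_dry": sc.fresh_to_dry} for sc in constants.values()]
    ).to_csv(path, index=False)


def read_feeding(
    path: str | Path,
    constants: dict[str, SpeciesConstants],
    frass_profiles: dict[tuple[str, int], ChemProfile] | None = None,
    leaf_profiles: dict[str, ChemProfile] | None = None,
) -> list[FeedingRecord]:
    """Read feeding records; compute W_Leaf eagerly and flag non-feeders.

    ``leaf_profiles`` maps species id -> the feeding tree's profile (C_Leaf);
    ``frass_profiles`` is keyed by (caterpillar, phase).  Records whose
    computed eaten dry mass is <= 0 are flagged ``excluded`` — kept in the
    returned list, never silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=object)
    for col in FEEDING_COLS:
        if col not in df.columns:
            raise ParseError(f"{path.name}: required column {col!r} absent")
    if df.empty:
        logger.warning("%s: empty feeding table", path.name)
        return []
    records: list[FeedingRecord] = []
    for idx in df.index:
        phase = int(df.at[idx, "phase"])
        p1 = str(df.at[idx, "phase1_host"])
        p2_raw = df.at[idx, "phase2_host"]
        p2 = None if (p2_raw is None or (isinstance(p2_raw, float) and math.isnan(p2_raw)) or p2_raw == "") else str(p2_raw)
        current = p2 if phase == 2 else p1
        if current not in constants:
            raise ValidationError(
                f"{path.name} row {idx}: species {current!r} not in species constants"
            )
        fresh = _cell_float(df, idx, "fresh_offered", "reject")
        dry_rem = _cell_float(df, idx, "dry_remaining", "reject")
        frass = _cell_float(df, idx, "frass_dry", "reject")
        w_leaf = consumed_dry(fresh, constants[current].fresh_to_dry, dry_rem)
        cat_id = str(df.at[idx, "caterpillar"])
        rec = FeedingRecord(
            caterpillar=cat_id,
            phase=phase,
            phase1_host=p1,
            phase2_host=p2,
            fresh_offered=fresh,
            dry_remaining=dry_rem,
            frass_dry=frass,
            frass_profile=(frass_profiles or {}).get((cat_id, phase)),
            leaf_profile=(leaf_profiles or {}).get(current),
            w_leaf=max(w_leaf, 0.0),
            excluded=w_leaf <= 0,
        )
        if rec.excluded:
            logger.info("record %s phase %d excluded: non-feeder (W_Leaf=%.4g g)", cat_id, phase, w_leaf)
        records.append(rec)
    return records


def write_feeding(records: list[FeedingRecord], path: str | Path) -> None:
    rows = [
        {
            "caterpillar": r.caterpillar,
            "phase": r.phase,
            "phase1_host": r.phase1_host,
            "phase2_host": r.phase2_host or "",
            "fresh_offered": r.fresh_offered,
            "dry_remaining": r.dry_remaining,
            "frass_dry": r.frass_dry,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_report(directory: str | Path, catalog: CompoundCatalog) -> dict:
    """Schema report for an experiment directory (the CLI ``validate`` command)."""
    directory = Path(directory)
    report: dict[str, object] = {"directory": str(directory), "files": {}, "ok": True}
    expected = ["leaves.csv", "frass.csv", "feeding.csv", "species.csv"]
    constants: dict[str, SpeciesConstants] = {}
    for name in expected:
        f = directory / name
        entry: dict[str, object] = {"present": f.exists()}
        if not f.exists():
            report["ok"] = False
            report["files"][name] = entry  # type: ignore[index]
            continue
        try:
            if name == "leaves.csv":
                samples = read_profiles(f, "leaf", catalog)
                entry["rows"] = len(samples)
                entry["feeding_trees"] = sorted(
                    {s.species for s in samples if s.is_feeding_tree}
                )
            elif name == "frass.csv":
                profiles = read_profiles(f, "frass", catalog)
                entry["rows"] = len(profiles)
            elif name == "species.csv":
                constants = read_species_constants(f)
                entry["rows"] = len(constants)
            elif name == "feeding.csv":
                recs = read_feeding(f, constants or read_species_constants(directory / "species.csv"))
                entry["rows"] = len(recs)
                entry["excluded_non_feeders"] = sum(r.excluded for r in recs)
        except Exception as exc:  # report, don't raise: this is a linter
            entry["error"] = f"{type(exc).__name__}: {exc}"
            report["ok"] = False
        report["files"][name] = entry  # type: ignore[index]
    return report
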