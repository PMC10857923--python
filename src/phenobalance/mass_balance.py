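"""Per-compound ingestion-excretion mass balances and their derived summaries.

The central quantity is, for one caterpillar and one chemical variable,

    X = W_Leaf * C_Leaf - W_Frass * C_Frass        [mg]

where W are dry masses (g) of leaf tissue eaten and frass produced and C
are concentrations (mg/g) in the feeding tree's leaves and in that
caterpillar's frass.  X near zero means the compound passed through the gut
unchanged (passive excretion); X > 0 means part of the ingested amount was
lost in the gut (taken up, oxidized, hydrolyzed, adsorbed — the budget
cannot tell these apart); X < 0 means the compound was produced in the gut
from other substrates (e.g. an isomer enriched by alkaline isomerization).

The two activity measures run through the same W*C arithmetic as the
compounds: an "amount of activity" in mg of standard equivalents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ACTIVITY_IDS, CompoundCatalog
from .types import FeedingRecord, LeafSample, active_records

#: default tolerance for calling a balance "passive": |X| within 10% of the
#: ingested amount, with an absolute floor of 0.01 mg for trace compounds
DEFAULT_EPSILON = 0.1
DEFAULT_FLOOR_MG = 0.01

FATES = ("passive", "lost", "produced")


@dataclass
class MassBalance:
    """One caterpillar x one variable budget line."""

    caterpillar: str
    variable: str
    ingested: float
    excreted: float
    X: float
    fate: str


@dataclass
class BiomassResult:
    """Retained leaf biomass of one caterpillar against its one-host baseline."""

    caterpillar: str
    retained: float
    baseline_mean: float
    relative_decrease: float


def consumed_dry(fresh_offered: float, fresh_to_dry: float, dry_remaining: float) -> float:
    """Dry mass of leaf tissue eaten: ``fresh_offered/fresh_to_dry - dry_remaining``.

    A non-positive result signals a non-feeding caterpillar; callers flag the
    record excluded rather than dropping it.
    """
    if not fresh_to_dry > 1:
        raise ValueError(f"fresh_to_dry must exceed 1, got {fresh_to_dry}")
    return fresh_offered / fresh_to_dry - dry_remaining


def classify_fate(
    X: float,
    ingested: float,
    epsilon: float = DEFAULT_EPSILON,
    floor_mg: float = DEFAULT_FLOOR_MG,
) -> str:
    """Label a balance passive / lost / produced.

    The passive band is ``|X| <= epsilon * max(ingested, floor_mg)``; above
    it X > 0 is "lost" (removed in the gut) and X < 0 "produced".
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    threshold = epsilon * max(ingested, floor_mg)
    if abs(X) <= threshold:
        return "passive"
    return "lost" if X > 0 else "produced"


def balance(
    record: FeedingRecord,
    catalog: CompoundCatalog,
    epsilon: float = DEFAULT_EPSILON,
    floor_mg: float = DEFAULT_FLOOR_MG,
) -> list[MassBalance]:
    """Budget every compound and both activities for one feeding record."""
    if record.excluded:
        raise ValueError(f"record {record.caterpillar!r} is excluded (non-feeder)")
    if record.leaf_profile is None:
        raise ValueError(f"record {record.caterpillar!r} has no linked leaf profile")
    if record.frass_profile is None:
        raise ValueError(f"record {record.caterpillar!r} has no linked frass profile")
    out = []
    for var in catalog.ids + list(ACTIVITY_IDS):
        ingested = record.w_leaf * record.leaf_profile.value(var)
        excreted = record.w_frass * record.frass_profile.value(var)
        X = ingested - excreted
        out.append(
            MassBalance(
                caterpillar=record.caterpillar,
                variable=var,
                ingested=ingested,
                excreted=excreted,
                X=X,
                fate=classify_fate(X, ingested, epsilon, floor_mg),
            )
        )
    return out


def balance_table(
    records: list[FeedingRecord],
    catalog: CompoundCatalog,
    epsilon: float = DEFAULT_EPSILON,
    floor_mg: float = DEFAULT_FLOOR_MG,
) -> pd.DataFrame:
    """Tidy budget table for many records.

    Columns: caterpillar, phase, phase1_host, phase2_host, current_host,
    variable, ingested, excreted, X, fate.  Excluded records are skipped.
    """
    rows = []
    for rec in active_records(records):
        for mb in balance(rec, catalog, epsilon, floor_mg):
            rows.append(
                {
                    "caterpillar": mb.caterpillar,
                    "phase": rec.phase,
                    "phase1_host": rec.phase1_host,
                    "phase2_host": rec.phase2_host,
                    "current_host": rec.current_host,
                    "variable": mb.variable,
                    "ingested": mb.ingested,
                    "excreted": mb.excreted,
                    "X": mb.X,
                    "fate": mb.fate,
                }
            )
    return pd.DataFrame(rows)


def percent_loss(ingested: float, excreted: float) -> float:
    """Fraction of the ingested amount lost leaf->frass: ``1 - excreted/ingested``.

    Negative values mean an increase (production in the gut).  Undefined for
    ingested == 0; returns NaN as the missing marker.
    """
    if ingested < 0:
        raise ValueError("ingested must be >= 0")
    if ingested == 0:
        return math.nan
    return 1.0 - excreted / ingested


def prevalence_filter(
    frass_profiles,
    catalog: CompoundCatalog,
    min_conc: float = 0.01,
    min_prev: float = 0.25,
) -> list[str]:
    """Compounds detected (> ``min_conc`` mg/g) in a strict-majority share
    (> ``min_prev``) of the given frass profiles; activities are always kept.

    Both comparisons are strict, so a compound present in exactly 25% of the
    samples, or at exactly 0.01 mg/g, is excluded.
    """
    profiles = list(frass_profiles)
    if not profiles:
        raise ValueError("prevalence_filter needs at least one frass profile")
    n = len(profiles)
    kept = []
    for cid in catalog.ids:
        share = sum(p.value(cid) > min_conc for p in profiles) / n
        if share > min_prev:
            kept.append(cid)
    return kept + list(ACTIVITY_IDS)


def retained_biomass(
    records: list[FeedingRecord],
) -> tuple[list[BiomassResult], dict[str, float]]:
    """Retained biomass of phase-2 caterpillars vs their one-host baseline.

    For each phase-2 host the baseline is the mean retained biomass of the
    caterpillars that stayed on that host (one-host larvae);
    ``relative_decrease = (baseline_mean - retained) / baseline_mean`` for
    every phase-2 caterpillar on that host.  Returns the per-caterpillar
    results and the per-host baseline means.
    """
    phase2 = [r for r in active_records(records) if r.phase == 2]
    if not phase2:
        raise ValueError("no active phase-2 records")
    baselines: dict[str, float] = {}
    for host in sorted({r.phase2_host for r in phase2}):  # type: ignore[arg-type]
        one_host = [r.retained for r in phase2 if r.phase2_host == host and r.is_one_host]
        if one_host:
            baselines[host] = float(np.mean(one_host))
    results = []
    for r in phase2:
        host = r.phase2_host
        if host not in baselines:
            continue  # no one-host group on this host; caller warned upstream
        base = baselines[host]
        results.append(
            BiomassResult(
                caterpillar=r.caterpillar,
                retained=r.retained,
                baseline_mean=base,
                relative_decrease=(base - r.retained) / base,
            )
        )
    if not results:
        raise ValueError("no phase-2 host has a one-host baseline group")
    return results, baselines


def retention_estimates(balances: pd.DataFrame, catalog: CompoundCatalog) -> pd.DataFrame:
    """Estimate per-compound gut retention fractions from a budget table.

    The retention fraction of a compound is the fraction of the ingested
    amount removed in the gut; its natural estimator is the across-caterpillar
    mean of X/ingested.  Members of an isomer family are pooled first
    (isomerization shuffles mass within a family while conserving its total,
    so only the family-level fraction is identifiable) and the family
    estimate is reported for each member.

    Returns a frame indexed by (current_host, variable) with columns
    lambda_hat and n.
    """
    df = balances[balances["variable"].isin(catalog.ids)].copy()
    fam_of = {c.id: c.isomer_family for c in catalog}
    df["group"] = df["variable"].map(lambda v: fam_of[v] or v)
    pooled = (
        df.groupby(["current_host", "caterpillar", "group"])[["ingested", "X"]]
        .sum()
        .reset_index()
    )
    pooled = pooled[pooled["ingested"] > 0]
    pooled["ratio"] = pooled["X"] / pooled["ingested"]
    agg = pooled.groupby(["current_host", "group"])["ratio"].agg(["mean", "count"])
    rows = []
    for (host, group), row in agg.iterrows():
        members = (
            catalog.family_members(group) if group in catalog.families else [group]
        )
        for cid in members:
            rows.append(
                {
                    "current_host": host,
                    "variable": cid,
                    "lambda_hat": row["mean"],
                    "n": int(row["count"]),
                }
            )
    return pd.DataFrame(rows).set_index(["current_host", "variable"])


def fate_summary(balances: pd.DataFrame) -> pd.DataFrame:
    """Count fates per current host and variable (tidy summary for reports)."""
    return (
        balances.groupby(["current_host", "variable", "fate"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(FATES), fill_value=0)
    )
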