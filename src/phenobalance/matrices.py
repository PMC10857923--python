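"""Response-matrix builders shared by the ordination and dissimilarity code.

Two bases recur in every analysis: ``"compounds"`` (one column per catalog
compound) and ``"subgroups_activities"`` (the four subgroup totals plus the
two activity measures).  Activities are carried alongside compounds but are
never summed into a subgroup total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import ACTIVITY_IDS, SUBGROUP_TOTAL_IDS, SUBGROUPS, CompoundCatalog
from .types import ChemProfile, LeafSample

BASES = ("compounds", "subgroups_activities")


def _profile_row(profile: ChemProfile, catalog: CompoundCatalog, basis: str) -> dict:
    if basis == "compounds":
        return {cid: profile.value(cid) for cid in catalog.ids}
    row = {}
    for sg in SUBGROUPS:
        row[SUBGROUP_TOTAL_IDS[sg]] = sum(
            profile.value(cid) for cid in catalog.subgroup_members(sg)
        )
    row["Ox"] = profile.oxidative_activity
    row["PP"] = profile.protein_precipitation
    return row


def profile_matrix(
    profiles: dict | list,
    catalog: CompoundCatalog,
    basis: str = "compounds",
) -> pd.DataFrame:
    """Samples x variables concentration matrix from profiles.

    ``profiles`` may be a mapping key -> ChemProfile or a list of
    (key, ChemProfile) pairs; the keys become the row index.
    """
    if basis not in BASES:
        raise ValueError(f"unknown basis {basis!r}; expected one of {BASES}")
    items = profiles.items() if isinstance(profiles, dict) else list(profiles)
    rows = {key: _profile_row(p, catalog, basis) for key, p in items}
    return pd.DataFrame.from_dict(rows, orient="index")


def leaf_matrix(
    leaves: list[LeafSample], catalog: CompoundCatalog, basis: str = "compounds"
) -> pd.DataFrame:
    """Concentration matrix of leaf samples, indexed by (species, tree)."""
    return profile_matrix(
        [((s.species, s.tree), s.profile) for s in leaves], catalog, basis
    )


def balance_matrix(
    balances: pd.DataFrame,
    catalog: CompoundCatalog,
    basis: str = "compounds",
    variables: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Caterpillars x variables matrix of ingested-excreted differences (X).

    Returns (X matrix, metadata frame) with aligned row order; metadata
    carries phase, hosts.  On the subgroup basis the X of a subgroup total
    is the sum of its members' X (the budget is linear in concentrations).
    ``variables`` restricts the compound columns (e.g. a prevalence-filtered
    set); activity columns named in it are kept on the compounds basis too.
    """
    if basis not in BASES:
        raise ValueError(f"unknown basis {basis!r}; expected one of {BASES}")
    wide = balances.pivot_table(index="caterpillar", columns="variable", values="X")
    meta = (
        balances[["caterpillar", "phase", "phase1_host", "phase2_host", "current_host"]]
        .drop_duplicates("caterpillar")
        .set_index("caterpillar")
    )
    if basis == "compounds":
        cols = variables if variables is not None else catalog.ids + list(ACTIVITY_IDS)
        cols = [c for c in cols if c in wide.columns]
        X = wide[cols]
    else:
        data = {}
        for sg in SUBGROUPS:
            members = [c for c in catalog.subgroup_members(sg) if c in wide.columns]
            data[SUBGROUP_TOTAL_IDS[sg]] = wide[members].sum(axis=1)
        for act in ACTIVITY_IDS:
            if act in wide.columns:
                data[act] = wide[act]
        X = pd.DataFrame(data, index=wide.index)
    meta = meta.loc[X.index]
    return X, meta


def combined_leaf_frass_matrix(
    leaves: list[LeafSample],
    frass_profiles: dict,
    catalog: CompoundCatalog,
    basis: str = "compounds",
) -> tuple[pd.DataFrame, pd.Series]:
    """Stack leaf and frass concentration profiles into one matrix.

    Returns the matrix and a parallel "kind" series ("leaf"/"frass"); used
    for the combined PCA exploring leaf-vs-frass variation.
    """
    leaf = leaf_matrix(leaves, catalog, basis)
    leaf.index = [f"leaf:{sp}:{tr}" for sp, tr in leaf.index]
    frass = profile_matrix(
        {f"frass:{c}:{p}": prof for (c, p), prof in frass_profiles.items()},
        catalog,
        basis,
    )
    mat = pd.concat([leaf, frass])
    kind = pd.Series(
        ["leaf"] * len(leaf) + ["frass"] * len(frass), index=mat.index, name="kind"
    )
    return mat, kind
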