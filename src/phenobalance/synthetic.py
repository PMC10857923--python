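"""Synthetic two-phase feeding experiments with known ground truth.

The generator emulates the design of a two-phase host-transfer trial with
three broadleaf tree species and a polyphagous caterpillar: leaf chemistry
is sampled from ~10 trees per species, each species' caterpillars feed on a
single designated feeding tree, and after Phase I each host's cohort is
split three ways (stay, or transfer to one of the other two hosts).

Ground truth per caterpillar and compound is the gut retention fraction
lambda: the fraction of the ingested amount removed in the gut, so the
excreted amount is ingested * (1 - lambda).  On top of that, members of an
isomer family are redistributed to the equilibrium fractions dictated by
the true gut pH while conserving the family's total mass — giving the
negative balances (gut production of minor isomers) seen in real frass.
Bulk mass bookkeeping is separate: frass dry mass is leaf dry mass eaten
times (1 - assimilation); the polyphenol mass fraction is treated as
negligible for bulk mass.

Noise model: lognormal multiplicative noise with unit mean everywhere a
coefficient of variation is configured (concentrations are positive and
right-skewed), plus Gaussian jitter on per-caterpillar retention
(``lambda_sd``) and assimilation (``assimilation_sd``).  Habituation enters
as ``lambda_two_host = clip(lambda_one_host - habituation_delta, 0, 1)``:
caterpillars facing a novel host metabolize less of what they ingest.
Transferred caterpillars also assimilate less bulk mass, in proportion to
the Bray-Curtis dissimilarity between the old and new hosts' base leaf
profiles (``transfer_assimilation_drop``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import SUBGROUPS, CompoundCatalog, default_catalog
from .gut_ph import IsomerModel, simulate_fractions
from .rank_stats import bray_curtis
from .types import ChemProfile, Experiment, FeedingRecord, LeafSample, SpeciesConstants

SPECIES = ("acer", "carpinus", "quercus")

#: study-design defaults: trees sampled per species and caterpillars per
#: Phase-I host, with the Phase-II three-way split (stay / two transfers)
DEFAULT_TREES = {"acer": 10, "carpinus": 9, "quercus": 11}
DEFAULT_PHASE1_COUNTS = {"acer": 59, "carpinus": 59, "quercus": 65}
DEFAULT_PHASE2_COUNTS = {
    ("acer", "acer"): 10,
    ("acer", "carpinus"): 17,
    ("acer", "quercus"): 17,
    ("carpinus", "acer"): 14,
    ("carpinus", "carpinus"): 8,
    ("carpinus", "quercus"): 9,
    ("quercus", "acer"): 17,
    ("quercus", "carpinus"): 14,
    ("quercus", "quercus"): 9,
}
DEFAULT_FRESH_TO_DRY = {"acer": 2.6, "carpinus": 2.4, "quercus": 2.8}

#: linear weights mapping subgroup totals (mg/g) to the two activity
#: measures; oxidative activity is dominated by hydrolyzable tannins,
#: protein precipitation by proanthocyanidins
OX_WEIGHTS = {
    "cinnamic_acid_derivative": 0.30,
    "flavonoid": 0.20,
    "hydrolyzable_tannin": 0.80,
    "proanthocyanidin": 0.10,
}
PP_WEIGHTS = {
    "cinnamic_acid_derivative": 0.05,
    "flavonoid": 0.10,
    "hydrolyzable_tannin": 0.40,
    "proanthocyanidin": 0.70,
}


def default_base_concentrations(catalog: CompoundCatalog) -> dict[str, dict[str, float]]:
    """Species-specific baseline leaf concentrations (mg/g dry weight).

    Each species has its own support set — many compounds occur in, or
    dominate, one host only: the maple is rich in flavonoid glycosides,
    caffeoylquinic acids and procyanidin-type proanthocyanidins; the
    hornbeam is dominated by geraniin with coumaroylquinic and quercetin
    glycosides; the oak by C-glycosidic ellagitannins.
    """
    base = {sp: {cid: 0.0 for cid in catalog.ids} for sp in SPECIES}
    base["acer"].update(
        {
            "CA1": 6.0, "CA2": 2.0, "CA3": 1.5, "CA6": 1.0,
            "FL1": 8.0, "FL2": 5.0, "FL3": 3.0, "FL4": 0.5, "FL9": 0.8,
            "PC1": 3.0, "PC2": 2.5, "PC3": 2.0, "PC4": 1.5,
            "HH6": 0.3,
        }
    )
    base["carpinus"].update(
        {
            "CA1": 5.0, "CA2": 1.5, "CA3": 1.0, "CA4": 2.0, "CA5": 1.0,
            "FL5": 4.0, "FL6": 3.0, "FL7": 2.0,
            "PC1": 1.5, "PC2": 1.0, "PC3": 0.8, "PC4": 0.5,
            "HH1": 25.0, "HH6": 0.5,
        }
    )
    base["quercus"].update(
        {
            "CA1": 1.5, "CA2": 0.5, "CA3": 0.3,
            "FL4": 1.0, "FL5": 1.5, "FL8": 0.8,
            "PC1": 1.0, "PC2": 0.8,
            "HH2": 12.0, "HH3": 10.0, "HH4": 6.0, "HH5": 3.0, "HH6": 1.0,
        }
    )
    return base


def default_retention(catalog: CompoundCatalog) -> dict[str, dict[str, float]]:
    """Baseline one-host gut retention fractions per current host x compound.

    Hydrolyzable tannins are strongly removed (oxidized/hydrolyzed) in the
    alkaline gut — geraniin almost completely, the oak ellagitannins by
    70-90%; flavan-3-ols and procyanidins disappear on the enzymatically
    active hornbeam; flavonoid glycosides are largely passively excreted.
    Isomer-family members share one value: only the family-level fraction
    is identifiable once isomerization shuffles mass within the family.
    """
    lam = {sp: {cid: 0.10 for cid in catalog.ids} for sp in SPECIES}
    for sp in SPECIES:
        for cid in ("CA1", "CA2", "CA3"):
            lam[sp][cid] = 0.30
        lam[sp]["CA4"] = lam[sp]["CA5"] = 0.25
        lam[sp]["CA6"] = 0.20
        lam[sp]["HH6"] = 0.30
    lam["carpinus"]["HH1"] = 0.98
    lam["quercus"].update({"HH2": 0.70, "HH3": 0.80, "HH4": 0.87, "HH5": 0.75})
    for cid in ("PC1", "PC2", "PC3", "PC4"):
        lam["carpinus"][cid] = 0.90
        lam["acer"][cid] = 0.05
        lam["quercus"][cid] = 0.40
    for cid in ("FL1", "FL2", "FL3"):
        lam["acer"][cid] = 0.20
    for cid in ("FL5", "FL6", "FL7"):
        lam["carpinus"][cid] = 0.15
    return lam


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic experiment; defaults are the study design."""

    catalog: CompoundCatalog = field(default_factory=default_catalog)
    species: tuple[str, ...] = SPECIES
    trees_per_species: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TREES))
    phase1_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PHASE1_COUNTS))
    phase2_counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_PHASE2_COUNTS)
    )
    fresh_to_dry: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRESH_TO_DRY))
    base_concentrations: dict[str, dict[str, float]] | None = None
    retention: dict[str, dict[str, float]] | None = None

    # noise levels (lognormal CVs unless stated otherwise)
    tree_cv: float = 0.30
    batch_cv: float = 0.15
    measurement_cv: float = 0.10
    lambda_sd: float = 0.05  # Gaussian sd of per-caterpillar retention
    assimilation_sd: float = 0.05  # Gaussian sd of per-caterpillar assimilation

    # biology
    assimilation_mean: float = 0.36
    habituation_delta: float = 0.15
    transfer_assimilation_drop: float = 0.08  # x Bray-Curtis(old, new)
    gut_ph_true: float = 9.9
    isomer_model: IsomerModel = field(default_factory=IsomerModel)

    # feeding bookkeeping
    mean_consumed_dry: float = 0.20  # g dry leaf eaten per 24 h
    consumption_cv: float = 0.30
    leftover_dry: float = 0.30  # g dry leaf left uneaten (sets fresh_offered)

    def __post_init__(self) -> None:
        if self.base_concentrations is None:
            self.base_concentrations = default_base_concentrations(self.catalog)
        if self.retention is None:
            self.retention = default_retention(self.catalog)
        for name in ("tree_cv", "batch_cv", "measurement_cv", "lambda_sd", "assimilation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.assimilation_mean < 1:
            raise ValueError("assimilation_mean must be in (0, 1)")
        for sp, table in self.retention.items():
            for cid, lamb in table.items():
                if not 0 <= lamb <= 1:
                    raise ValueError(f"retention[{sp}][{cid}] = {lamb} outside [0, 1]")

    def with_overrides(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Everything needed to verify downstream estimates against the generator."""

    gut_ph_true: float
    tree_multipliers: dict[tuple[str, str], np.ndarray]  # (species, tree) -> per-compound
    lambda_realized: dict[tuple[str, int], dict[str, float]]  # (caterpillar, phase)
    assimilation_realized: dict[tuple[str, int], float]
    lambda_base: dict[str, dict[str, float]]
    habituation_delta: float

    def to_json_dict(self) -> dict:
        return {
            "gut_ph_true": self.gut_ph_true,
            "habituation_delta": self.habituation_delta,
            "lambda_base": self.lambda_base,
            "assimilation_realized": {
                f"{c}|{p}": v for (c, p), v in self.assimilation_realized.items()
            },
            "lambda_realized": {
                f"{c}|{p}": v for (c, p), v in self.lambda_realized.items()
            },
            "tree_multipliers": {
                f"{sp}|{tr}": m.tolist() for (sp, tr), m in self.tree_multipliers.items()
            },
        }


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _activities(conc: dict[str, float], catalog: CompoundCatalog) -> tuple[float, float]:
    totals = {
        sg: sum(conc[cid] for cid in catalog.subgroup_members(sg)) for sg in SUBGROUPS
    }
    ox = sum(OX_WEIGHTS[sg] * totals[sg] for sg in SUBGROUPS)
    pp = sum(PP_WEIGHTS[sg] * totals[sg] for sg in SUBGROUPS)
    return ox, pp


def generate_leaves(
    config: GeneratorConfig, seed: int | np.random.Generator
) -> tuple[list[LeafSample], dict[tuple[str, str], np.ndarray]]:
    """Leaf samples for every tree of every species; tree 1 is the feeding tree.

    Returns the samples and the per-(species, tree) concentration
    multipliers (the leaf-side ground truth).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    catalog = config.catalog
    samples: list[LeafSample] = []
    multipliers: dict[tuple[str, str], np.ndarray] = {}
    for sp in config.species:
        base = np.array([config.base_concentrations[sp][cid] for cid in catalog.ids])
        for t in range(config.trees_per_species[sp]):
            tree = f"{sp}_T{t + 1:02d}"
            mult = _unit_mean_lognormal(rng, config.tree_cv, len(catalog))
            conc_vec = base * mult
            conc = dict(zip(catalog.ids, conc_vec))
            ox, pp = _activities(conc, catalog)
            samples.append(
                LeafSample(
                    species=sp,
                    tree=tree,
                    is_feeding_tree=(t == 0),
                    profile=ChemProfile(
                        concentrations=conc, oxidative_activity=ox, protein_precipitation=pp
                    ),
                )
            )
            multipliers[(sp, tree)] = mult
    return samples, multipliers


def _host_dissimilarity_from_base(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    ids = config.catalog.ids
    vecs = {
        sp: np.array([config.base_concentrations[sp][cid] for cid in ids])
        for sp in config.species
    }
    out = {}
    for a in config.species:
        for b in config.species:
            out[(a, b)] = 0.0 if a == b else bray_curtis(vecs[a], vecs[b])
    return out


def _simulate_caterpillar(
    config: GeneratorConfig,
    rng: np.random.Generator,
    cat_id: str,
    phase: int,
    p1: str,
    p2: str | None,
    leaf_conc: np.ndarray,
    dissim: dict[tuple[str, str], float],
) -> tuple[FeedingRecord, dict[str, float], float]:
    catalog = config.catalog
    current = p2 if phase == 2 else p1
    ratio = config.fresh_to_dry[current]
    two_host = phase == 2 and p2 != p1

    w_leaf = config.mean_consumed_dry * float(
        _unit_mean_lognormal(rng, config.consumption_cv, 1)[0]
    )
    dry_remaining = config.leftover_dry
    fresh_offered = (w_leaf + dry_remaining) * ratio

    batch = _unit_mean_lognormal(rng, config.batch_cv, len(catalog))
    ingested = w_leaf * leaf_conc * batch  # mg, what the gut actually saw

    base_lam = np.array([config.retention[current][cid] for cid in catalog.ids])
    if two_host:
        base_lam = np.clip(base_lam - config.habituation_delta, 0.0, 1.0)
    jitter = rng.normal(0.0, config.lambda_sd, len(catalog)) if config.lambda_sd else 0.0
    lam = np.clip(base_lam + jitter, 0.0, 1.0)

    excreted = ingested * (1.0 - lam)
    # alkaline isomerization: redistribute each family's surviving mass to
    # the equilibrium fractions at the true gut pH
    for family, members in catalog.families.items():
        model = config.isomer_model
        if model.family != family:
            continue
        idx = [catalog.ids.index(m) for m in members]
        total = excreted[idx].sum()
        if total > 0:
            excreted[idx] = total * simulate_fractions(model, config.gut_ph_true)

    drop = config.transfer_assimilation_drop * dissim[(p1, current)] if two_host else 0.0
    assim = float(
        np.clip(
            config.assimilation_mean - drop
            + (rng.normal(0.0, config.assimilation_sd) if config.assimilation_sd else 0.0),
            0.05,
            0.95,
        )
    )
    w_frass = w_leaf * (1.0 - assim)

    c_frass_true = excreted / w_frass
    c_frass = c_frass_true * _unit_mean_lognormal(rng, config.measurement_cv, len(catalog))
    conc = dict(zip(catalog.ids, c_frass))
    ox_true, pp_true = _activities(dict(zip(catalog.ids, c_frass_true)), catalog)
    act_noise = _unit_mean_lognormal(rng, config.measurement_cv, 2)
    frass_profile = ChemProfile(
        concentrations=conc,
        oxidative_activity=ox_true * float(act_noise[0]),
        protein_precipitation=pp_true * float(act_noise[1]),
    )

    leaf_profile = ChemProfile(
        concentrations=dict(zip(catalog.ids, leaf_conc)),
        oxidative_activity=_activities(dict(zip(catalog.ids, leaf_conc)), catalog)[0],
        protein_precipitation=_activities(dict(zip(catalog.ids, leaf_conc)), catalog)[1],
    )
    record = FeedingRecord(
        caterpillar=cat_id,
        phase=phase,
        phase1_host=p1,
        phase2_host=p2,
        fresh_offered=fresh_offered,
        dry_remaining=dry_remaining,
        frass_dry=w_frass,
        frass_profile=frass_profile,
        leaf_profile=leaf_profile,
        w_leaf=w_leaf,
        excluded=False,
    )
    return record, dict(zip(catalog.ids, lam)), assim


def generate_feeding(
    config: GeneratorConfig,
    leaves: list[LeafSample],
    seed: int | np.random.Generator,
    tree_multipliers: dict[tuple[str, str], np.ndarray] | None = None,
) -> tuple[list[FeedingRecord], SyntheticTruth]:
    """Both feeding phases for all caterpillars, plus the ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    catalog = config.catalog
    feeding_conc = {}
    for leaf in leaves:
        if leaf.is_feeding_tree:
            feeding_conc[leaf.species] = np.array(
                [leaf.profile.value(cid) for cid in catalog.ids]
            )
    missing = [sp for sp in config.species if sp not in feeding_conc]
    if missing:
        raise ValueError(f"no feeding tree designated for species: {missing}")
    dissim = _host_dissimilarity_from_base(config)

    records: list[FeedingRecord] = []
    lambda_realized: dict[tuple[str, int], dict[str, float]] = {}
    assim_realized: dict[tuple[str, int], float] = {}

    pools: dict[str, list[str]] = {}
    for sp in config.species:
        ids = [f"{sp}_c{i + 1:03d}" for i in range(config.phase1_counts[sp])]
        pools[sp] = ids
        for cat_id in ids:
            rec, lam, assim = _simulate_caterpillar(
                config, rng, cat_id, 1, sp, None, feeding_conc[sp], dissim
            )
            records.append(rec)
            lambda_realized[(cat_id, 1)] = lam
            assim_realized[(cat_id, 1)] = assim

    for sp in config.species:
        cursor = 0
        for target in config.species:
            n = config.phase2_counts.get((sp, target), 0)
            group = pools[sp][cursor : cursor + n]
            if len(group) < n:
                raise ValueError(
                    f"phase2_counts for {(sp, target)} exceed the phase-1 pool of {sp!r}"
                )
            cursor += n
            for cat_id in group:
                rec, lam, assim = _simulate_caterpillar(
                    config, rng, cat_id, 2, sp, target, feeding_conc[target], dissim
                )
                records.append(rec)
                lambda_realized[(cat_id, 2)] = lam
                assim_realized[(cat_id, 2)] = assim

    truth = SyntheticTruth(
        gut_ph_true=config.gut_ph_true,
        tree_multipliers=tree_multipliers or {},
        lambda_realized=lambda_realized,
        assimilation_realized=assim_realized,
        lambda_base={sp: dict(config.retention[sp]) for sp in config.species},
        habituation_delta=config.habituation_delta,
    )
    return records, truth


def generate_experiment(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[Experiment, SyntheticTruth]:
    """One full experiment: leaves, both feeding phases, species constants."""
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(seed)
    leaf_seed, feed_seed = ss.spawn(2)
    leaves, multipliers = generate_leaves(config, np.random.default_rng(leaf_seed))
    records, truth = generate_feeding(
        config, leaves, np.random.default_rng(feed_seed), tree_multipliers=multipliers
    )
    constants = {
        sp: SpeciesConstants(species=sp, fresh_to_dry=config.fresh_to_dry[sp])
        for sp in config.species
    }
    experiment = Experiment(
        catalog=config.catalog, leaves=leaves, records=records, constants=constants
    )
    return experiment, truth


def write_experiment(experiment: Experiment, truth: SyntheticTruth, directory) -> None:
    """Write an experiment in the CSV/JSON schema the readers consume."""
    import json
    from pathlib import Path

    from . import io as pio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    experiment.catalog.to_json(directory / "catalog.json")
    pio.write_profiles(experiment.leaves, directory / "leaves.csv", experiment.catalog)
    frass = {
        (r.caterpillar, r.phase): r.frass_profile
        for r in experiment.records
        if r.frass_profile is not None
    }
    pio.write_profiles(frass, directory / "frass.csv", experiment.catalog)
    pio.write_feeding(experiment.records, directory / "feeding.csv")
    pio.write_species_constants(experiment.constants, directory / "species.csv")
    (directory / "truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=2) + "\n"
    )


def load_experiment(directory) -> Experiment:
    """Read back an experiment directory written by :func:`write_experiment`."""
    from pathlib import Path

    from . import io as pio
    from .catalog import CompoundCatalog

    directory = Path(directory)
    catalog = CompoundCatalog.from_json(directory / "catalog.json")
    leaves = pio.read_profiles(directory / "leaves.csv", "leaf", catalog)
    frass = pio.read_profiles(directory / "frass.csv", "frass", catalog)
    constants = pio.read_species_constants(directory / "species.csv")
    leaf_profiles = {
        s.species: s.profile for s in leaves if s.is_feeding_tree
    }
    records = pio.read_feeding(
        directory / "feeding.csv", constants, frass_profiles=frass, leaf_profiles=leaf_profiles
    )
    return Experiment(catalog=catalog, leaves=leaves, records=records, constants=constants)
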