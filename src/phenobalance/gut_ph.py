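"""Gut-pH inference from the redistribution of interconvertible isomers.

Caffeoylquinic acids (and related cinnamic acid esters) isomerize in
alkaline conditions: the equilibrium mixture of the positional isomers
shifts with pH.  A caterpillar's frass therefore carries a pH signature in
the *fractions* of an isomer family, independent of how much of the family
was ingested.  This module matches observed frass fractions against a
pH-indexed model of the equilibrium fractions over the alkaline range
(pH 9.0-11.0) typical of lepidopteran midguts.

The pH-to-fractions mapping itself is pluggable.  The default is a
logistic interpolation between two anchor compositions:

    f(pH) = normalize(anchor_low + (anchor_high - anchor_low)
                      * logistic((pH - midpoint) / slope))

with anchors at the ends of the grid.  Published equilibrium tables can be
supplied as alternative anchors (or via ``IsomerModel.from_json``) to
reproduce a specific laboratory calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import CompoundCatalog
from .types import ChemProfile

GRID_LOW, GRID_HIGH, GRID_STEP = 9.0, 11.0, 0.01


class EstimationError(ValueError):
    """Observed data cannot support a pH estimate (family absent, etc.)."""


def _logistic(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)  # overflow-safe branch for large negative arguments
    return ez / (1.0 + ez)


@dataclass
class IsomerModel:
    """pH-indexed equilibrium fractions of one isomer family.

    ``anchor_low`` and ``anchor_high`` are the limiting compositions toward
    the low and high ends of the pH grid; both must be nonnegative and sum
    to 1.  ``midpoint`` and ``slope`` (pH units) place and scale the
    logistic transition between them.
    """

    family: str = "caffeoyl_quinic_acid"
    anchor_low: np.ndarray = field(
        default_factory=lambda: np.array([0.55, 0.30, 0.15])
    )
    anchor_high: np.ndarray = field(
        default_factory=lambda: np.array([0.10, 0.25, 0.65])
    )
    midpoint: float = 10.0
    slope: float = 0.25
    grid: tuple[float, float, float] = (GRID_LOW, GRID_HIGH, GRID_STEP)

    def __post_init__(self) -> None:
        self.anchor_low = np.asarray(self.anchor_low, dtype=float)
        self.anchor_high = np.asarray(self.anchor_high, dtype=float)
        for name, anchor in (("anchor_low", self.anchor_low), ("anchor_high", self.anchor_high)):
            if anchor.ndim != 1 or len(anchor) < 2:
                raise ValueError(f"{name} must be a vector of >= 2 fractions")
            if np.any(anchor < 0) or not math.isclose(anchor.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if self.anchor_low.shape != self.anchor_high.shape:
            raise ValueError("anchors must have the same length")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    @property
    def grid_points(self) -> np.ndarray:
        low, high, step = self.grid
        n = int(round((high - low) / step)) + 1
        return np.round(low + step * np.arange(n), 10)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family": self.family,
            "anchor_low": self.anchor_low.tolist(),
            "anchor_high": self.anchor_high.tolist(),
            "midpoint": self.midpoint,
            "slope": self.slope,
            "grid": list(self.grid),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "IsomerModel":
        payload = json.loads(Path(path).read_text())
        payload["grid"] = tuple(payload.get("grid", (GRID_LOW, GRID_HIGH, GRID_STEP)))
        return cls(**payload)


def simulate_fractions(model: IsomerModel, ph: float) -> np.ndarray:
    """Equilibrium isomer fractions at a pH inside the model grid."""
    low, high, _ = model.grid
    if not (low <= ph <= high):
        raise ValueError(f"pH {ph} outside model range [{low}, {high}]")
    w = _logistic((ph - model.midpoint) / model.slope)
    raw = model.anchor_low + (model.anchor_high - model.anchor_low) * w
    return raw / raw.sum()


def frass_fractions(
    profile: ChemProfile, catalog: CompoundCatalog, family: str
) -> np.ndarray:
    """Observed fractions of an isomer family in one frass profile.

    Family member concentrations normalized to sum 1, in catalog order;
    NaN vector (missing marker) if every member is zero.
    """
    members = catalog.family_members(family)
    values = np.array([profile.value(m) for m in members], dtype=float)
    total = values.sum()
    if total == 0:
        return np.full(len(members), np.nan)
    return values / total


def estimate_ph(model: IsomerModel, observed_fractions) -> tuple[float, float]:
    """Grid-search pH estimate: argmin Euclidean distance to the model curve.

    Observed fractions are renormalized on entry; ties break toward the
    lower pH (np.argmin returns the first minimum on the ascending grid).
    Returns (pH estimate, fit distance).
    """
    obs = np.asarray(observed_fractions, dtype=float)
    if obs.shape != model.anchor_low.shape:
        raise EstimationError(
            f"observed vector has length {len(obs)}, model family has {len(model.anchor_low)}"
        )
    if np.any(~np.isfinite(obs)) or obs.sum() <= 0:
        raise EstimationError("observed fractions are missing or all zero")
    obs = obs / obs.sum()
    grid = model.grid_points
    curve = np.stack([simulate_fractions(model, p) for p in grid])
    dist = np.linalg.norm(curve - obs, axis=1)
    i = int(np.argmin(dist))
    return float(grid[i]), float(dist[i])


def estimate_ph_per_caterpillar(
    frass_profiles: dict,
    catalog: CompoundCatalog,
    model: IsomerModel | None = None,
) -> "pd.DataFrame":
    """Per-caterpillar pH estimates from a frass-profile mapping.

    Keys of ``frass_profiles`` are (caterpillar, phase).  Caterpillars whose
    family members are all zero are skipped.  Returns a frame with columns
    caterpillar, phase, ph, distance.
    """
    import pandas as pd

    model = model or IsomerModel()
    rows = []
    for (cat_id, phase), profile in frass_profiles.items():
        obs = frass_fractions(profile, catalog, model.family)
        if np.any(~np.isfinite(obs)):
            continue
        ph, dist = estimate_ph(model, obs)
        rows.append({"caterpillar": cat_id, "phase": phase, "ph": ph, "distance": dist})
    return pd.DataFrame(rows)
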