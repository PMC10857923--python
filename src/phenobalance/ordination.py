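"""Unconstrained (PCA) and factor-constrained (RDA) ordination.

Both are implemented directly on the centered data matrix.  RDA with a
single factor as the constraint projects the centered response matrix onto
the group-indicator column space (k-1 degrees of freedom for k levels): the
fitted values are the group means, the constrained inertia is their sum of
squares, and

    R^2      = constrained / total
    R^2_adj  = 1 - (1 - R^2) * (n - 1) / (n - k)      (Ezekiel correction)
    pseudo-F = (constrained / (k - 1)) / (residual / (n - k))

Significance is assessed by a Monte-Carlo permutation test: response rows
are permuted uniformly at random and p = (1 + #{F* >= F_obs}) / (n_perm + 1),
so the smallest attainable p with 999 permutations is 0.001.  Ties
F* == F_obs count as exceedances (the conservative convention).

R^2_adj can be negative when the constraint explains less than chance; it
is reported as computed, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ValidationError

#: tolerance for the exact inertia decomposition constrained + residual = total
_DECOMP_TOL = 1e-8


@dataclass
class OrdinationResult:
    """Eigenstructure and (for RDA) variance-partitioning statistics."""

    method: str
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    site_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    total_inertia: float
    constrained_inertia: float | None = None
    residual_inertia: float | None = None
    r2: float | None = None
    r2_adjusted: float | None = None
    pseudo_F: float | None = None
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    degenerate: bool = False
    groups: list[str] | None = None

    @property
    def adjusted_percent(self) -> float | None:
        """Adjusted variation explained, on the 0-100 scale reports use."""
        return None if self.r2_adjusted is None else 100.0 * self.r2_adjusted

    def summary(self) -> dict:
        out = {
            "method": self.method,
            "total_inertia": self.total_inertia,
            "eigenvalues": list(map(float, self.eigenvalues)),
            "proportion_explained": list(map(float, self.proportion_explained)),
        }
        for k in ("constrained_inertia", "residual_inertia", "r2", "r2_adjusted",
                  "pseudo_F", "p_perm", "n_perm", "seed"):
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v) if not isinstance(v, int) else v
        return out


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    m = np.asarray(matrix, dtype=float)
    return pd.DataFrame(m, columns=[f"v{j}" for j in range(m.shape[1])])


def log1p_transform(matrix):
    """Elementwise natural log(1 + x); rejects negative entries.

    The standard variance-stabilizing transform for right-skewed,
    zero-inflated concentration data.
    """
    df = _as_frame(matrix)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"log1p_transform requires nonnegative entries; "
            f"found {values[tuple(bad)]} at row {bad[0]}, column {df.columns[bad[1]]!r}"
        )
    out = pd.DataFrame(np.log1p(values), index=df.index, columns=df.columns)
    return out if isinstance(matrix, pd.DataFrame) else out.to_numpy()


def signed_log1p(matrix):
    """sign(x) * log(1+|x|): a log-like transform for signed balance matrices."""
    df = _as_frame(matrix)
    v = df.to_numpy(dtype=float)
    out = pd.DataFrame(np.sign(v) * np.log1p(np.abs(v)), index=df.index, columns=df.columns)
    return out if isinstance(matrix, pd.DataFrame) else out.to_numpy()


def pca(matrix, center: bool = True, scale: bool = False) -> OrdinationResult:
    """Principal components of a samples x variables matrix.

    Eigenvalues are those of the covariance of the (optionally centered and
    unit-scaled) columns; axes are ordered by decreasing eigenvalue.  A
    constant matrix yields all-zero eigenvalues and a ``degenerate`` flag
    (explained proportions are then undefined and set to NaN).
    """
    df = _as_frame(matrix)
    Y = df.to_numpy(dtype=float)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("pca needs at least 2 rows")
    if center:
        Y = Y - Y.mean(axis=0)
    if scale:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = Y / sd
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    eig = s**2 / (n - 1)
    total = float(eig.sum())
    degenerate = total <= 0
    prop = np.full_like(eig, np.nan) if degenerate else eig / total
    site = pd.DataFrame(
        U * s, index=df.index, columns=[f"PC{i+1}" for i in range(len(s))]
    )
    var = pd.DataFrame(
        Vt.T, index=df.columns, columns=[f"PC{i+1}" for i in range(len(s))]
    )
    return OrdinationResult(
        method="pca",
        eigenvalues=eig,
        proportion_explained=prop,
        site_scores=site,
        variable_scores=var,
        total_inertia=total,
        degenerate=degenerate,
    )


def _group_indices(groups) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(np.asarray(groups), sort=True)
    return codes, list(levels)


def _constrained_ss(Yc: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    """Sum of squares of the group-mean fit of a centered response matrix."""
    k = len(counts)
    sums = np.zeros((k, Yc.shape[1]))
    np.add.at(sums, codes, Yc)
    return float((sums**2 / counts[:, None]).sum())


def rda(
    Y,
    groups,
    n_perm: int = 0,
    seed: int | None = None,
) -> OrdinationResult:
    """Redundancy analysis of a response matrix constrained by one factor.

    ``groups`` is a length-n factor; ``n_perm > 0`` additionally runs the
    Monte-Carlo permutation test for the pseudo-F.  Eigenvalues and axis
    scores come from the SVD of the fitted (group-mean) matrix.
    """
    df = _as_frame(Y)
    Ym = df.to_numpy(dtype=float)
    n = Ym.shape[0]
    codes, levels = _group_indices(groups)
    if len(codes) != n:
        raise ValueError("groups length must match the number of rows")
    k = len(levels)
    if k < 2:
        raise ValueError("rda needs a factor with at least 2 levels")
    if n <= k:
        raise ValueError(f"rda needs more rows ({n}) than factor levels ({k})")
    counts = np.bincount(codes, minlength=k).astype(float)

    Yc = Ym - Ym.mean(axis=0)
    total = float((Yc**2).sum())
    # fitted values of the one-factor linear model are the group means
    sums = np.zeros((k, Yc.shape[1]))
    np.add.at(sums, codes, Yc)
    means = sums / counts[:, None]
    fitted = means[codes]
    constrained = float((fitted**2).sum())
    residual = total - constrained
    assert abs((constrained + residual) - total) <= _DECOMP_TOL * max(total, 1.0)

    r2 = constrained / total if total > 0 else np.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    F_obs = (constrained / (k - 1)) / (residual / (n - k)) if residual > 0 else np.inf

    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(k - 1, Ym.shape[1])
    eig = (s**2 / (n - 1))[:n_axes]
    site = pd.DataFrame(
        (U * s)[:, :n_axes], index=df.index, columns=[f"RDA{i+1}" for i in range(n_axes)]
    )
    var = pd.DataFrame(
        Vt.T[:, :n_axes], index=df.columns, columns=[f"RDA{i+1}" for i in range(n_axes)]
    )

    p_perm = None
    if n_perm > 0:
        p_perm = _perm_p(Yc, codes, counts, F_obs, n_perm=n_perm, seed=seed)

    return OrdinationResult(
        method="rda",
        eigenvalues=eig,
        proportion_explained=eig / total if total > 0 else np.full_like(eig, np.nan),
        site_scores=site,
        variable_scores=var,
        total_inertia=total,
        constrained_inertia=constrained,
        residual_inertia=residual,
        r2=float(r2),
        r2_adjusted=float(r2_adj),
        pseudo_F=float(F_obs),
        p_perm=p_perm,
        n_perm=n_perm if n_perm > 0 else None,
        seed=seed,
        groups=[str(l) for l in levels],
    )


def permutation_test(
    Y,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo permutation test of the RDA pseudo-F; returns (F_obs, p).

    Response rows are permuted uniformly at random ``n_perm`` times and
    p = (1 + #{F* >= F_obs}) / (n_perm + 1): the smallest attainable p is
    1/(n_perm + 1), e.g. 0.001 with 999 permutations.
    """
    result = rda(Y, groups, n_perm=n_perm, seed=seed)
    return result.pseudo_F, result.p_perm  # type: ignore[return-value]


def _perm_p(
    Yc: np.ndarray,
    codes: np.ndarray,
    counts: np.ndarray,
    F_obs: float,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Free row permutation; F is compared on the constrained-SS scale
    (for fixed group sizes F is monotone in the constrained sum of squares,
    and permuting rows leaves total inertia unchanged)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n, _ = Yc.shape
    k = len(counts)
    total = float((Yc**2).sum())
    # invert F to the constrained-SS threshold once; permuting rows leaves
    # total inertia unchanged
    dfc, dfr = k - 1, n - k
    if np.isinf(F_obs):
        ss_threshold = total
    else:
        ss_threshold = total * F_obs / (F_obs + dfr / dfc)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss = _constrained_ss(Yc[perm], codes, counts)
        if ss >= ss_threshold - 1e-12 * max(total, 1.0):
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Ezekiel-corrected variation explained for a k-level factor constraint."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k)
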