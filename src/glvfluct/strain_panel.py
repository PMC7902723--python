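"""Domain types for strains, pH responses and interaction matrices.

Growth parameters are tabulated on a discrete pH grid and linearly
interpolated on demand.  Interaction coefficients quantify the effect of
one strain on another's carrying capacity (dimensionless; -1 means
complete niche overlap, positive values mean facilitation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHGrid",
    "PHResponse",
    "Strain",
    "InteractionMatrix",
    "Community",
    "default_grid",
    "interp_response",
    "infer_interaction",
    "predict_supernatant_capacity",
    "screen_instability",
    "interaction_at_ph",
    "read_panel_csv",
    "write_panel_csv",
    "read_interaction_csv",
    "write_interaction_csv",
]

#: Default pH characterization grid: 5.1 to 7.5 at 0.3 intervals (9 points).
DEFAULT_GRID_VALUES = np.round(np.arange(5.1, 7.5 + 1e-9, 0.3), 10)

#: pH coefficients below this value are flagged as strong inhibition.
STRONG_INHIBITION_CUTOFF = -1.2


@dataclass(frozen=True)
class PHGrid:
    """Ordered pH points on which growth parameters are tabulated."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("pH grid needs at least 2 points")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("pH grid must be strictly increasing")
        if vals[0] < 0 or vals[-1] > 14:
            raise ValueError("pH grid must lie within [0, 14]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def clamp(self, p):
        """Clamp pH value(s) to the grid range."""
        return np.clip(p, self.lo, self.hi)


def default_grid() -> PHGrid:
    return PHGrid(DEFAULT_GRID_VALUES.copy())


@dataclass(frozen=True)
class PHResponse:
    """Per-strain growth rate r(p) [1/h] and carrying capacity K(p) [OD]."""

    grid: PHGrid
    r: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "K", K)
        n = len(self.grid)
        if r.shape != (n,) or K.shape != (n,):
            raise ValueError("r and K must match the grid length")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("growth rates must be finite and non-negative")
        if np.any(K <= 0) or not np.all(np.isfinite(K)):
            raise ValueError("carrying capacities must be finite and positive")

    def __call__(self, p: float) -> tuple[float, float]:
        return interp_response(self, p)


@dataclass(frozen=True)
class Strain:
    """An in silico strain: a labelled pH response tied to a base species."""

    id: str
    species: str
    response: PHResponse


@dataclass
class InteractionMatrix:
    """Square matrix of interaction coefficients.

    ``c[i, j]`` is the effect of strain/species ``j`` on ``i``.  The
    diagonal is pinned at -1 (complete niche overlap with self).  An
    optional slope matrix makes coefficients linear in pH around the
    reference pH ``p0``.
    """

    c: np.ndarray
    slopes: np.ndarray | None = None
    p0: float = 7.2
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("interaction matrix must be square")
        if not np.allclose(np.diag(c), -1.0, atol=1e-12):
            raise ValueError("interaction matrix diagonal must be exactly -1")
        np.fill_diagonal(c, -1.0)
        self.c = c
        if self.slopes is not None:
            m = np.asarray(self.slopes, dtype=float)
            if m.shape != c.shape:
                raise ValueError("slope matrix must match the coefficient matrix shape")
            # diagonal self-interaction never drifts with pH
            m = m.copy()
            np.fill_diagonal(m, 0.0)
            self.slopes = m
        if self.labels and len(self.labels) != c.shape[0]:
            raise ValueError("labels must match matrix size")

    @property
    def n(self) -> int:
        return self.c.shape[0]

    def at_ph(self, p: float) -> np.ndarray:
        return interaction_at_ph(self, p)


@dataclass
class Community:
    """A set of strains with densities (OD) and a strain-level matrix."""

    strains: list[Strain]
    densities: np.ndarray
    interactions: InteractionMatrix

    def __post_init__(self) -> None:
        dens = np.asarray(self.densities, dtype=float)
        if dens.shape != (len(self.strains),):
            raise ValueError("densities must have one entry per strain")
        if np.any(dens < 0):
            raise ValueError("densities must be non-negative")
        if self.interactions.n != len(self.strains):
            raise ValueError("interaction matrix size must match strain count")
        ids = [s.id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise ValueError("strain ids must be unique within a community")
        self.densities = dens

    @property
    def n(self) -> int:
        return len(self.strains)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.strains]

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.strains]

    @property
    def grid(self) -> PHGrid:
        return self.strains[0].response.grid

    def r_table(self) -> np.ndarray:
        """(n_strains, n_grid) growth-rate table."""
        return np.vstack([s.response.r for s in self.strains])

    def k_table(self) -> np.ndarray:
        """(n_strains, n_grid) carrying-capacity table."""
        return np.vstack([s.response.K for s in self.strains])

    def subset(self, idx: np.ndarray) -> "Community":
        """Community restricted to strains at positions ``idx``."""
        idx = np.asarray(idx)
        C = self.interactions
        sub = InteractionMatrix(
            C.c[np.ix_(idx, idx)].copy(),
            slopes=None if C.slopes is None else C.slopes[np.ix_(idx, idx)].copy(),
            p0=C.p0,
            labels=[self.strains[i].id for i in idx],
        )
        return Community(
            [self.strains[i] for i in idx], self.densities[idx].copy(), sub
        )


# ---------------------------------------------------------------------------
# operations


def interp_response(response: PHResponse, p: float) -> tuple[float, float]:
    """Piecewise-linear growth rate and carrying capacity at pH ``p``.

    Exact at grid nodes; clamped to the nearest end value outside the
    measured range.
    """
    if not math.isfinite(p):
        raise ValueError(f"pH must be finite, got {p!r}")
    g = response.grid.values
    rate = float(np.interp(p, g, response.r))
    cap = float(np.interp(p, g, response.K))
    return rate, cap


def infer_interaction(
    K_ij: float,
    K_i: float,
    K_j: float,
    sd_K_ij: float | None = None,
    sd_K_i: float | None = None,
    sd_K_j: float | None = None,
):
    """Interaction coefficient from a supernatant (spent-media) assay.

    ``c_ij = (K_ij - K_i) / K_j`` where ``K_ij`` is the carrying capacity
    of strain i grown in the spent medium of strain j.  If standard
    deviations are supplied, a first-order (delta-method) uncertainty is
    returned as ``(c_ij, sd_c_ij)``.
    """
    if K_j <= 0:
        raise ValueError("K_j must be positive (division by donor capacity)")
    if K_i <= 0:
        raise ValueError("K_i must be positive")
    if K_ij < 0:
        raise ValueError("K_ij must be non-negative")
    c = (K_ij - K_i) / K_j
    if sd_K_ij is None and sd_K_i is None and sd_K_j is None:
        return c
    s_ij = 0.0 if sd_K_ij is None else sd_K_ij
    s_i = 0.0 if sd_K_i is None else sd_K_i
    s_j = 0.0 if sd_K_j is None else sd_K_j
    var = (s_ij**2 + s_i**2) / K_j**2 + (c * s_j / K_j) ** 2
    return c, math.sqrt(var)


def predict_supernatant_capacity(K_i: float, c_ij: float, K_j: float) -> float:
    """Forward model of the supernatant assay: ``K_ij = K_i + c_ij * K_j``."""
    if K_i <= 0 or K_j <= 0:
        raise ValueError("carrying capacities must be positive")
    return K_i + c_ij * K_j


def screen_instability(C: InteractionMatrix | np.ndarray) -> list[tuple[int, int]]:
    """Pairs at risk of runaway growth under mutual facilitation.

    A pair (i, j) is flagged when ``c_ij > 0``, ``c_ji > 0`` and
    ``c_ij * c_ji > 1``: the carrying-capacity terms then fail to bound
    the populations and densities diverge.
    """
    c = C.c if isinstance(C, InteractionMatrix) else np.asarray(C, dtype=float)
    n = c.shape[0]
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            if c[i, j] > 0 and c[j, i] > 0 and c[i, j] * c[j, i] > 1:
                flagged.append((i, j))
    return flagged


def interaction_at_ph(C: InteractionMatrix, p: float) -> np.ndarray:
    """Effective coefficient matrix at pH ``p``.

    With slopes present, ``c_ij(p) = c_ij(p0) + m_ij * (p - p0)``; the
    diagonal stays -1.  Without slopes the matrix is returned unchanged.
    """
    if C.slopes is None:
        return C.c
    eff = C.c + C.slopes * (p - C.p0)
    np.fill_diagonal(eff, -1.0)
    return eff


# ---------------------------------------------------------------------------
# file formats: delimited text, one row per strain / labelled square matrix


def write_panel_csv(path, strains: list[Strain]) -> None:
    grid = strains[0].response.grid.values
    cols = {"strain_id": [s.id for s in strains], "species": [s.species for s in strains]}
    for k, p in enumerate(grid):
        cols[f"r@{p:g}"] = [s.response.r[k] for s in strains]
    for k, p in enumerate(grid):
        cols[f"K@{p:g}"] = [s.response.K[k] for s in strains]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_panel_csv(path) -> list[Strain]:
    df = pd.read_csv(path)
    r_cols = [c for c in df.columns if c.startswith("r@")]
    k_cols = [c for c in df.columns if c.startswith("K@")]
    grid = PHGrid(np.array([float(c[2:]) for c in r_cols]))
    strains = []
    for _, row in df.iterrows():
        resp = PHResponse(
            grid,
            row[r_cols].to_numpy(dtype=float),
            row[k_cols].to_numpy(dtype=float),
        )
        strains.append(Strain(str(row["strain_id"]), str(row["species"]), resp))
    return strains


def write_interaction_csv(path, C: InteractionMatrix, slopes_path=None) -> None:
    labels = C.labels or [str(i) for i in range(C.n)]
    pd.DataFrame(C.c, index=labels, columns=labels).to_csv(path)
    if slopes_path is not None and C.slopes is not None:
        pd.DataFrame(C.slopes, index=labels, columns=labels).to_csv(slopes_path)


def read_interaction_csv(path, slopes_path=None, p0: float = 7.2) -> InteractionMatrix:
    df = pd.read_csv(path, index_col=0)
    slopes = None
    if slopes_path is not None:
        slopes = pd.read_csv(slopes_path, index_col=0).to_numpy(dtype=float)
    return InteractionMatrix(
        df.to_numpy(dtype=float), slopes=slopes, p0=p0, labels=[str(c) for c in df.columns]
    )
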