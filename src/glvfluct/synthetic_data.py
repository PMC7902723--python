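"""Synthetic strain panels and in silico strain-space expansion.

The generator produces a base panel of species (smooth pH-response
curves plus an interaction matrix with a controlled facilitation
structure) and expands it into strains by bounded random modulation of
the species-level parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .strain_panel import (
    Community,
    InteractionMatrix,
    PHGrid,
    PHResponse,
    Strain,
    default_grid,
    screen_instability,
    write_interaction_csv,
    write_panel_csv,
)

__all__ = [
    "PanelSpec",
    "ModulationSpec",
    "generate_base_panel",
    "modulate_strain",
    "sample_assemblage",
    "save_panel",
]

_EPS = 1e-9  # floor for modulated growth parameters


@dataclass(frozen=True)
class PanelSpec:
    """Statistical recipe for a synthetic base-species panel."""

    n_species: int = 6
    n_positive_interactions: int = 3
    strong_inhibition_fraction: float = 0.1
    positive_cap: float = 0.3
    negative_range: tuple[float, float] = (-1.5, -0.05)
    r_range: tuple[float, float] = (0.0, 1.0)
    k_range: tuple[float, float] = (0.05, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        n_off = self.n_species * (self.n_species - 1)
        if self.n_positive_interactions > n_off:
            raise ValueError("more positive interactions than off-diagonal slots")
        # one positive direction per unordered pair at most (no mutual facilitation)
        if self.n_positive_interactions > n_off // 2:
            raise ValueError(
                "cannot place positives without mutual facilitation"
            )
        if not 0 <= self.strong_inhibition_fraction <= 1:
            raise ValueError("strong_inhibition_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ModulationSpec:
    """Bounded multiplicative strain-level parameter variation."""

    f_p: float = 0.20
    per_point: bool = False  # modulate whole curves (default) or per grid point
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.f_p < 1:
            raise ValueError("f_p must be in [0, 1)")


def _positive_graph_has_cycle(pos: set[tuple[int, int]], n: int) -> bool:
    """DFS cycle check on the directed facilitation graph (tiny n)."""
    adj = [[] for _ in range(n)]
    for i, j in pos:
        adj[j].append(i)  # j facilitates i: edge j -> i
    color = [0] * n
    def visit(u: int) -> bool:
        color[u] = 1
        for v in adj[u]:
            if color[v] == 1:
                return True
            if color[v] == 0 and visit(v):
                return True
        color[u] = 2
        return False
    return any(color[u] == 0 and visit(u) for u in range(n))


def _smooth_curve(rng: np.random.Generator, grid: np.ndarray, lo: float, hi: float,
                  min_val: float) -> np.ndarray:
    """Unimodal bump on the grid, rescaled into [max(lo, min_val), hi]."""
    span = grid[-1] - grid[0]
    peak = rng.uniform(grid[0], grid[-1])
    width = rng.uniform(0.25, 1.0) * span
    base = np.exp(-0.5 * ((grid - peak) / width) ** 2)
    top = rng.uniform(0.5 * (lo + hi), hi)
    bottom = rng.uniform(max(lo, min_val), top)
    base = (base - base.min()) / (base.max() - base.min() + 1e-12)
    return bottom + (top - bottom) * base


def generate_base_panel(
    spec: PanelSpec, max_tries: int = 1000
) -> tuple[list[PHResponse], InteractionMatrix]:
    """Generate species pH responses and an interaction matrix.

    The matrix has diagonal -1, exactly ``n_positive_interactions``
    positive off-diagonals (magnitude <= ``positive_cap``), the
    remaining off-diagonals negative, a controlled fraction of them
    below the strong-inhibition cutoff of -1.2, and no mutual or cyclic
    facilitation.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    grid = default_grid()
    g = grid.values
    responses = []
    for _ in range(spec.n_species):
        r = _smooth_curve(rng, g, *spec.r_range, min_val=0.05)
        K = _smooth_curve(rng, g, *spec.k_range, min_val=0.05)
        responses.append(PHResponse(grid, r, K))

    n = spec.n_species
    offdiag = [(i, j) for i in range(n) for j in range(n) if i != j]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for _ in range(max_tries):
        # one direction per sampled unordered pair -> no mutual facilitation
        chosen_pairs = rng.choice(len(pairs), size=spec.n_positive_interactions,
                                  replace=False)
        pos = set()
        for k in chosen_pairs:
            i, j = pairs[k]
            pos.add((i, j) if rng.random() < 0.5 else (j, i))
        if _positive_graph_has_cycle(pos, n):
            continue
        c = np.zeros((n, n))
        neg_slots = [ij for ij in offdiag if ij not in pos]
        n_strong = int(round(spec.strong_inhibition_fraction * len(offdiag)))
        n_strong = min(n_strong, len(neg_slots))
        strong_idx = set(
            rng.choice(len(neg_slots), size=n_strong, replace=False).tolist()
        )
        lo_neg, hi_neg = spec.negative_range
        for k, (i, j) in enumerate(neg_slots):
            if k in strong_idx:
                c[i, j] = rng.uniform(lo_neg, min(hi_neg, -1.2))
            else:
                c[i, j] = rng.uniform(max(lo_neg, -1.2), hi_neg)
        for i, j in pos:
            c[i, j] = rng.uniform(0.01, spec.positive_cap)
        np.fill_diagonal(c, -1.0)
        C = InteractionMatrix(c, labels=[f"sp{i}" for i in range(n)])
        if not screen_instability(C):
            return responses, C
    raise RuntimeError("could not generate a panel without runaway pairs")


def modulate_strain(
    species_response: PHResponse,
    species: str,
    strain_id: str,
    spec: ModulationSpec,
    rng: np.random.Generator,
) -> Strain:
    """Create a strain by bounded multiplicative modulation of a species.

    A single multiplier drawn from Uniform(1 - f_p, 1 + f_p) scales the
    whole r curve and an independent one the whole K curve, preserving
    the measured response shape (per-grid-point modulation available via
    ``spec.per_point``).
    """
    f = spec.f_p
    if spec.per_point:
        npts = len(species_response.grid)
        u_r = rng.uniform(1 - f, 1 + f, size=npts)
        u_k = rng.uniform(1 - f, 1 + f, size=npts)
    else:
        u_r = rng.uniform(1 - f, 1 + f)
        u_k = rng.uniform(1 - f, 1 + f)
    r = np.maximum(species_response.r * u_r, _EPS)
    K = np.maximum(species_response.K * u_k, _EPS)
    return Strain(strain_id, species, PHResponse(species_response.grid, r, K))


def sample_assemblage(
    panel: tuple[list[PHResponse], InteractionMatrix],
    n_strains: int,
    spec: ModulationSpec,
    s0: float = 1e-4,
    rng: np.random.Generator | None = None,
) -> Community:
    """Random initial assemblage of modulated strains.

    Species are drawn uniformly with replacement; every strain is
    independently modulated; the strain-level matrix is built from the
    species-level entries with independent per-entry modulation.
    Distinct strains of the same species start from a base coefficient
    of -1 (complete niche overlap) before modulation.
    """
    if n_strains < 1:
        raise ValueError("assemblage needs at least one strain")
    responses, C = panel
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_sp = len(responses)
    picks = rng.integers(0, n_sp, size=n_strains)
    strains = [
        modulate_strain(
            responses[sp], f"sp{sp}", f"sp{sp}.s{k}", spec, rng
        )
        for k, sp in enumerate(picks)
    ]
    f = spec.f_p
    c = np.empty((n_strains, n_strains))
    for a in range(n_strains):
        for b in range(n_strains):
            if a == b:
                c[a, b] = -1.0
                continue
            base = -1.0 if picks[a] == picks[b] else C.c[picks[a], picks[b]]
            c[a, b] = base * rng.uniform(1 - f, 1 + f)
    slopes = None
    if C.slopes is not None:
        slopes = np.zeros_like(c)
        for a in range(n_strains):
            for b in range(n_strains):
                if a != b and picks[a] != picks[b]:
                    slopes[a, b] = C.slopes[picks[a], picks[b]]
    strain_C = InteractionMatrix(
        c, slopes=slopes, p0=C.p0, labels=[s.id for s in strains]
    )
    return Community(strains, np.full(n_strains, s0), strain_C)


def save_panel(outdir, responses: list[PHResponse], C: InteractionMatrix,
               spec: PanelSpec) -> None:
    """Write panel CSVs plus a JSON provenance sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    strains = [
        Strain(f"sp{i}", f"sp{i}", resp) for i, resp in enumerate(responses)
    ]
    write_panel_csv(outdir / "panel.csv", strains)
    write_interaction_csv(outdir / "interactions.csv", C)
    with open(outdir / "panel_meta.json", "w") as fh:
        json.dump({"generator": "glvfluct.synthetic_data", "spec": asdict(spec)}, fh,
                  indent=2)
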