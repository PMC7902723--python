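"""Enrichment-style assembly of stable communities.

An initial assemblage of strains is simulated for ``n_gen`` generations;
survivors form the candidate community, which must be stationary and
robust to a +/-50% change in the dilution rate before being used in
fluctuation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import PHDriver, SimulationConfig, Trajectory, simulate
from .strain_panel import Community

__all__ = [
    "StableCommunity",
    "enrich",
    "is_stable",
    "dilution_robustness_filter",
    "build_stable_ensemble",
]

STABILITY_WINDOW_GENS = 10
STABILITY_TOL = 1e-3
ROBUSTNESS_THRESHOLD = 0.2


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    tot = x.sum() + y.sum()
    if tot == 0:
        return 0.0
    return 1.0 - 2.0 * np.minimum(x, y).sum() / tot


def _facilitation_fraction(c: np.ndarray) -> float:
    n = c.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    return float((c[off] > 0).sum() / off.sum())


@dataclass
class StableCommunity:
    """Survivors of an enrichment run with their steady densities."""

    community: Community              # surviving strains only
    densities: np.ndarray             # steady densities, OD
    driver: PHDriver                  # environment used during assembly
    stable: bool
    seed: int | None = None
    panel_id: str | None = None
    assemblage_species: list[str] = field(default_factory=list)
    facilitation_fraction: float = 0.0
    initial_facilitation_fraction: float = 0.0

    @property
    def richness(self) -> int:
        return self.community.n

    @property
    def species(self) -> list[str]:
        return self.community.species

    def as_community(self) -> Community:
        """Surviving community with densities set to the steady state."""
        c = self.community
        return Community(c.strains, self.densities.copy(), c.interactions)


def is_stable(
    traj: Trajectory,
    config: SimulationConfig,
    window: int = STABILITY_WINDOW_GENS,
    tol: float = STABILITY_TOL,
) -> bool:
    """Stationarity check: composition drift over the last ``window``
    generations must be below ``tol`` Bray-Curtis."""
    gen = config.generation_time
    t_end = traj.times[-1]
    t_start = t_end - window * gen
    if t_start < traj.times[0] - 1e-9:
        raise ValueError("trajectory shorter than the stability window")
    a = traj.at_time(t_start)
    b = traj.at_time(t_end)
    if a.sum() == 0 and b.sum() == 0:
        return True
    if a.sum() == 0 or b.sum() == 0:
        return False
    return _bray_curtis(a / a.sum(), b / b.sum()) < tol


def enrich(
    assemblage: Community,
    driver: PHDriver,
    config: SimulationConfig,
    seed: int | None = None,
    panel_id: str | None = None,
    max_rounds: int = 4,
) -> StableCommunity:
    """Simulate an assemblage to (putative) stable coexistence.

    Runs rounds of ``n_gen`` generations, pruning extinct strains after
    each, until the surviving set stops changing (strains in slow decay
    need more than one round to clear the extinction threshold).
    Stationarity is then verified over the final generations;
    non-stationary outcomes are returned with ``stable=False`` and
    excluded downstream.
    """
    current = assemblage
    traj = None
    for _ in range(max_rounds):
        traj = simulate(current, driver, config)
        final = traj.final
        surviving = np.flatnonzero(final >= config.n_ext)
        if len(surviving) == current.n:
            current = Community(current.strains, final, current.interactions)
            break
        if len(surviving) == 0:
            current = current.subset(surviving)
            break
        current = current.subset(surviving)
        current.densities = final[surviving]
    stable = current.n > 0 and is_stable(traj, config)
    sub = current
    dens = current.densities.copy()
    init_ff = _facilitation_fraction(assemblage.interactions.c)
    ff = _facilitation_fraction(sub.interactions.c) if sub.n else 0.0
    return StableCommunity(
        community=sub,
        densities=dens,
        driver=driver,
        stable=stable,
        seed=seed,
        panel_id=panel_id,
        assemblage_species=assemblage.species,
        facilitation_fraction=ff,
        initial_facilitation_fraction=init_ff,
    )


def dilution_robustness_filter(
    sc: StableCommunity,
    config: SimulationConfig,
    factor: float = 0.5,
    threshold: float = ROBUSTNESS_THRESHOLD,
) -> bool:
    """Keep only communities insensitive to the dilution rate.

    The stable community is re-simulated at (1-factor) and (1+factor)
    times the nominal dilution rate; it passes when the worst-case
    Bray-Curtis distance of the resulting relative composition from the
    nominal one stays below ``threshold``.
    """
    if not sc.stable or sc.richness == 0:
        return False
    nominal = sc.densities / sc.densities.sum()
    comm = sc.as_community()
    for mult in (1.0 - factor, 1.0 + factor):
        cfg = config.with_(delta=config.delta * mult)
        traj = simulate(comm, sc.driver, cfg)
        final = traj.final
        if final.sum() < cfg.n_ext:
            return False  # washout at the modified dilution rate
        if _bray_curtis(final / final.sum(), nominal) >= threshold:
            return False
    return True


def build_stable_ensemble(
    panel,
    n_communities: int,
    config: SimulationConfig,
    mod_spec,
    master_seed: int = 0,
    driver: PHDriver | None = None,
    robustness: bool = True,
    max_attempts_factor: int = 20,
    panel_id: str | None = None,
):
    """Assemble robust stable communities until ``n_communities`` pass.

    Each attempt samples a fresh assemblage (child seed drawn from the
    master seed), enriches it and applies the stability and
    dilution-robustness filters.  Returns the accepted communities plus
    counters (attempted, stable, robust).
    """
    from .synthetic_data import sample_assemblage

    if driver is None:
        driver = PHDriver.constant(
            config.p0, clamp_lo=config.ph_min, clamp_hi=config.ph_max
        )
    rng = np.random.default_rng(master_seed)
    accepted: list[StableCommunity] = []
    attempted = n_stable = 0
    max_attempts = max_attempts_factor * n_communities
    while len(accepted) < n_communities and attempted < max_attempts:
        child = int(rng.integers(0, 2**63 - 1))
        assemblage = sample_assemblage(
            panel, config.n_c, mod_spec, s0=config.s0,
            rng=np.random.default_rng(child),
        )
        attempted += 1
        sc = enrich(assemblage, driver, config, seed=child, panel_id=panel_id)
        if not sc.stable:
            continue
        n_stable += 1
        if robustness and not dilution_robustness_filter(sc, config):
            continue
        accepted.append(sc)
    counts = {"attempted": attempted, "stable": n_stable, "accepted": len(accepted)}
    if len(accepted) < n_communities:
        raise RuntimeError(
            f"only {len(accepted)}/{n_communities} communities passed filters "
            f"after {attempted} attempts"
        )
    return accepted, counts
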