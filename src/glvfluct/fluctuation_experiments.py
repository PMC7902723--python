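"""Composition response of stable communities to temporal pH fluctuations.

The central measurement: simulate a stable community under a fluctuating
pH driver and under constant pH for the same duration, then compare the
cycle-averaged relative abundances with Bray-Curtis dissimilarity.
Sweeps over amplitude and frequency, interaction-matrix manipulations
(facilitation prevalence, uniform niche overlap), group comparisons and
the assembly-under-fluctuation richness analysis build on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import StableCommunity, build_stable_ensemble, enrich
from .dynamics import PHDriver, SimulationConfig, simulate
from .strain_panel import InteractionMatrix

__all__ = [
    "ExperimentSummary",
    "GroupComparison",
    "bray_curtis",
    "fluctuation_response",
    "amplitude_sweep",
    "frequency_sweep",
    "set_facilitation_prevalence",
    "set_niche_overlap",
    "classify_facilitation",
    "compare_groups",
    "richness_under_fluctuating_assembly",
    "cooperative_competitive_ensembles",
]

DISSIMILARITY_CUTOFF = 0.2
AVG_POINTS = 65


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``1 - 2*sum(min)/(sum(x)+sum(y))``.

    0 for identical compositions, 1 for disjoint support.  Vectors must
    share a strain universe (absent strains as zeros).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("compositions must have the same length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("compositions must be non-negative")
    tot = x.sum() + y.sum()
    if tot == 0:
        raise ValueError("both compositions are identically zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / tot)


@dataclass
class ExperimentSummary:
    """Long-format per-community results plus per-condition summaries."""

    values: pd.DataFrame           # columns: community, param, dissimilarity, ...
    summary: pd.DataFrame          # per-param median/mean/frac_below
    param: str                     # swept parameter name
    cutoff: float = DISSIMILARITY_CUTOFF


@dataclass
class GroupComparison:
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    u_statistic: float
    p_value: float
    n_a: int = 0
    n_b: int = 0


def _avg_window(driver: PHDriver, T: float) -> float:
    """Averaging window: one fluctuation period, capped at T/4."""
    if driver.kind == "constant" or driver.f <= 0:
        return T / 4.0
    return min(1.0 / driver.f, T / 4.0)


def _window_mean_relative(traj, t0: float) -> np.ndarray:
    """Time-averaged relative abundances over samples at t >= t0."""
    w = traj.window(t0)
    dens = w.densities
    totals = dens.sum(axis=0)
    if np.all(totals <= 0):
        return np.zeros(dens.shape[0])
    keep = totals > 0
    rel = dens[:, keep] / totals[keep]
    return rel.mean(axis=1)


def fluctuation_response(
    sc: StableCommunity,
    driver: PHDriver,
    config: SimulationConfig,
    mode: str = "cycle_avg",
    ref_composition: np.ndarray | None = None,
    T: float | None = None,
) -> float:
    """Bray-Curtis deviation of a community under a fluctuating pH.

    The community (at its stable densities) is simulated for ``n_gen``
    generations under ``driver`` and, as reference, under constant pH at
    the driver midpoint.  ``mode='cycle_avg'`` (default) compares
    relative abundances averaged over the final fluctuation period;
    ``mode='final'`` compares the final-instant compositions.  Complete
    washout under the driver returns 1.0.
    """
    if mode not in ("cycle_avg", "final"):
        raise ValueError(f"unknown mode {mode!r}")
    comm = sc.as_community()
    if comm.n == 0:
        raise ValueError("empty community")
    if T is None:
        T = config.total_time
    window = _avg_window(driver, T)
    traj = simulate(comm, driver, config, T=T, dense_window=window,
                    dense_points=AVG_POINTS)
    if traj.final.sum() < config.n_ext:
        return 1.0  # washout under the fluctuating environment
    if ref_composition is None:
        ref_driver = PHDriver.sinusoid(
            driver.p0, 0.0, driver.f if driver.f > 0 else 1.0,
            clamp_lo=driver.clamp_lo, clamp_hi=driver.clamp_hi,
        )
        ref_traj = simulate(comm, ref_driver, config, T=T, dense_window=window,
                            dense_points=AVG_POINTS)
        if mode == "cycle_avg":
            ref_composition = _window_mean_relative(ref_traj, T - window)
        else:
            tot = ref_traj.final.sum()
            ref_composition = ref_traj.final / tot if tot > 0 else ref_traj.final
    if mode == "cycle_avg":
        fluct = _window_mean_relative(traj, T - window)
    else:
        tot = traj.final.sum()
        fluct = traj.final / tot if tot > 0 else traj.final
    return bray_curtis(fluct, ref_composition)


def reference_composition(
    sc: StableCommunity, config: SimulationConfig, f: float,
    p0: float | None = None, mode: str = "cycle_avg",
) -> np.ndarray:
    """Constant-pH reference composition for a sweep at fixed frequency."""
    comm = sc.as_community()
    T = config.total_time
    drv = PHDriver.sinusoid(
        p0 if p0 is not None else config.p0, 0.0, f,
        clamp_lo=config.ph_min, clamp_hi=config.ph_max,
    )
    window = _avg_window(drv, T)
    traj = simulate(comm, drv, config, dense_window=window,
                    dense_points=AVG_POINTS)
    if mode == "final":
        tot = traj.final.sum()
        return traj.final / tot if tot > 0 else traj.final
    return _window_mean_relative(traj, T - window)


def amplitude_sweep(
    ensemble: list[StableCommunity],
    amplitudes,
    f: float,
    config: SimulationConfig,
    p0: float | None = None,
    cutoff: float = DISSIMILARITY_CUTOFF,
    mode: str = "cycle_avg",
) -> ExperimentSummary:
    """Dissimilarity of each community at each fluctuation amplitude."""
    p_mid = p0 if p0 is not None else config.p0
    rows = []
    for idx, sc in enumerate(ensemble):
        ref = reference_composition(sc, config, f, p0=p_mid, mode=mode)
        for dph in amplitudes:
            drv = PHDriver.sinusoid(p_mid, dph, f, clamp_lo=config.ph_min,
                                    clamp_hi=config.ph_max)
            d = fluctuation_response(sc, drv, config, mode=mode,
                                     ref_composition=ref)
            rows.append({"community": idx, "dph": dph, "dissimilarity": d,
                         "richness": sc.richness})
    return _summarize(pd.DataFrame(rows), "dph", cutoff)


def frequency_sweep(
    ensemble: list[StableCommunity],
    frequencies,
    dph: float,
    config: SimulationConfig,
    p0: float | None = None,
    cutoff: float = DISSIMILARITY_CUTOFF,
    mode: str = "cycle_avg",
) -> ExperimentSummary:
    """Dissimilarity of each community at each fluctuation frequency."""
    p_mid = p0 if p0 is not None else config.p0
    rows = []
    for idx, sc in enumerate(ensemble):
        for f in frequencies:
            drv = PHDriver.sinusoid(p_mid, dph, f, clamp_lo=config.ph_min,
                                    clamp_hi=config.ph_max)
            # fast forcing settles quickly; shorten the horizon so the
            # solver does not resolve thousands of redundant cycles
            T = config.total_time
            if f > 0.5:
                T = max(50.0, 0.5 * T / f, 20.0 / f)
            d = fluctuation_response(sc, drv, config, mode=mode, T=T)
            rows.append({"community": idx, "f": f, "dissimilarity": d,
                         "richness": sc.richness})
    return _summarize(pd.DataFrame(rows), "f", cutoff)


def _summarize(values: pd.DataFrame, param: str, cutoff: float) -> ExperimentSummary:
    grp = values.groupby(param)["dissimilarity"]
    summary = pd.DataFrame({
        "median": grp.median(),
        "mean": grp.mean(),
        "frac_below_cutoff": grp.apply(lambda s: float((s < cutoff).mean())),
        "n": grp.size(),
    }).reset_index()
    return ExperimentSummary(values, summary, param, cutoff)


def set_facilitation_prevalence(
    C: InteractionMatrix,
    fraction: float,
    magnitude_range: tuple[float, float] = (0.05, 0.3),
    rng: np.random.Generator | None = None,
) -> InteractionMatrix:
    """Set a given fraction of off-diagonal coefficients to be positive.

    Selects ``floor(fraction * n_offdiag)`` entries, at most one
    direction per unordered pair so that no mutual facilitation is ever
    created; 0.5 is therefore the maximum attainable prevalence.
    """
    if not 0 <= fraction <= 0.5:
        raise ValueError("facilitation prevalence must be in [0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(0)
    n = C.n
    n_off = n * (n - 1)
    k = int(np.floor(fraction * n_off))
    c = C.c.copy()
    if k == 0:
        return InteractionMatrix(c, slopes=None if C.slopes is None else C.slopes.copy(),
                                 p0=C.p0, labels=list(C.labels))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    order = rng.permutation(len(pairs))[:k]
    lo, hi = magnitude_range
    for idx in order:
        i, j = pairs[idx]
        # never create mutual facilitation: flip direction if needed
        if c[j, i] > 0:
            tgt = (j, i)
        elif c[i, j] > 0:
            tgt = (i, j)
        else:
            tgt = (i, j) if rng.random() < 0.5 else (j, i)
        c[tgt] = rng.uniform(lo, hi)
    return InteractionMatrix(c, slopes=None if C.slopes is None else C.slopes.copy(),
                             p0=C.p0, labels=list(C.labels))


def set_niche_overlap(C: InteractionMatrix, value: float) -> InteractionMatrix:
    """Uniform competition: all off-diagonals set to ``-|value|``."""
    n = C.n
    c = np.full((n, n), -abs(value))
    np.fill_diagonal(c, -1.0)
    return InteractionMatrix(c, p0=C.p0, labels=list(C.labels))


def classify_facilitation(sc: StableCommunity) -> float:
    """Fraction of positive off-diagonal interactions among members."""
    c = sc.community.interactions.c
    n = c.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    return float((c[off] > 0).sum() / off.sum())


def compare_groups(dissimilarities_a, dissimilarities_b) -> GroupComparison:
    """Medians, means and a two-sided Mann-Whitney U test."""
    a = np.asarray(dissimilarities_a, dtype=float)
    b = np.asarray(dissimilarities_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        u_statistic=float(u), p_value=float(p), n_a=a.size, n_b=b.size,
    )


def cooperative_competitive_ensembles(
    responses,
    base_C: InteractionMatrix,
    n_per_group: int,
    config: SimulationConfig,
    mod_spec,
    master_seed: int = 0,
) -> dict[str, list[StableCommunity]]:
    """Matched ensembles with 0% vs 50% species-level facilitation.

    Both groups share the base panel's pH responses and interaction
    magnitudes; the competitive matrix has every positive entry replaced
    by a negative draw, the cooperative one has facilitation injected at
    the maximum mutual-facilitation-free prevalence of 0.5.
    """
    rng = np.random.default_rng(master_seed)
    c = base_C.c.copy()
    pos = (c > 0) & ~np.eye(base_C.n, dtype=bool)
    c[pos] = rng.uniform(-1.2, -0.05, size=pos.sum())
    competitive_C = InteractionMatrix(c, p0=base_C.p0, labels=list(base_C.labels))
    cooperative_C = set_facilitation_prevalence(competitive_C, 0.5, rng=rng)
    out: dict[str, list[StableCommunity]] = {}
    for name, C in (("competitive", competitive_C), ("cooperative", cooperative_C)):
        ens, _ = build_stable_ensemble(
            (responses, C), n_per_group, config, mod_spec,
            master_seed=int(rng.integers(0, 2**63 - 1)), panel_id=name,
        )
        out[name] = ens
    return out


def richness_under_fluctuating_assembly(
    panel,
    amplitudes,
    frequencies,
    config: SimulationConfig,
    mod_spec,
    n_assemblages: int = 50,
    master_seed: int = 0,
    p0: float | None = None,
):
    """Assembly outcome under constant vs fluctuating pH, matched seeds.

    For each assemblage seed the same initial strain set is enriched
    under constant pH and under each sinusoidal driver on the
    (amplitude, frequency) grid.  Reports per-cell richness changes and
    tallies of which species are gained or lost relative to the
    constant-pH outcome.
    """
    from .synthetic_data import sample_assemblage

    p_mid = p0 if p0 is not None else config.p0
    rng = np.random.default_rng(master_seed)
    seeds = [int(rng.integers(0, 2**63 - 1)) for _ in range(n_assemblages)]
    const_drv = PHDriver.constant(p_mid, clamp_lo=config.ph_min,
                                  clamp_hi=config.ph_max)
    rows = []
    gained: dict[str, int] = {}
    lost: dict[str, int] = {}
    for seed in seeds:
        assemblage = sample_assemblage(
            panel, config.n_c, mod_spec, s0=config.s0,
            rng=np.random.default_rng(seed),
        )
        base = enrich(assemblage, const_drv, config, seed=seed)
        base_species = set(base.species)
        for dph in amplitudes:
            for f in frequencies:
                if dph == 0:
                    fl = base
                else:
                    drv = PHDriver.sinusoid(p_mid, dph, f,
                                            clamp_lo=config.ph_min,
                                            clamp_hi=config.ph_max)
                    fl = enrich(assemblage, drv, config, seed=seed)
                fl_species = set(fl.species)
                for sp in fl_species - base_species:
                    gained[sp] = gained.get(sp, 0) + 1
                for sp in base_species - fl_species:
                    lost[sp] = lost.get(sp, 0) + 1
                rows.append({
                    "seed": seed, "dph": dph, "f": f,
                    "richness_const": base.richness,
                    "richness_fluct": fl.richness,
                    "richness_delta": fl.richness - base.richness,
                    "gained": ",".join(sorted(fl_species - base_species)),
                    "lost": ",".join(sorted(base_species - fl_species)),
                })
    return pd.DataFrame(rows), {"gained": gained, "lost": lost}
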