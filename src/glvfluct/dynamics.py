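"""pH-dependent generalized Lotka-Volterra dynamics under dilution.

Each strain grows logistically with pH-dependent rate and capacity,
modulated by the weighted densities of the other strains, and is washed
out at a constant dilution rate:

    dS_i/dt = r_i(p) * [1 + (sum_j c_ij S_j) / K_i(p)] * S_i - delta * S_i

with c_ii = -1.  The pH is an arbitrary function of time (constant,
sinusoid or random telegraph), clamped to the characterized range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import ode

from .strain_panel import Community

try:  # optional speedup; the numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "PHDriver",
    "SimulationConfig",
    "Trajectory",
    "RunawayGrowthError",
    "ph_at",
    "glv_rhs",
    "simulate",
]

RUNAWAY_FACTOR = 1e3  # densities beyond this multiple of max K abort the run


class RunawayGrowthError(RuntimeError):
    """Raised when densities diverge (mutual facilitation instability)."""


@dataclass
class PHDriver:
    """Time -> pH function.

    kinds: ``constant`` (p0), ``sinusoid`` (p0 + dph*sin(2*pi*f*t)) and
    ``telegraph`` (random switching between p0-dph and p0+dph with
    exponential holding times of mean 1/f).  Output is clamped to
    [clamp_lo, clamp_hi], the characterized pH range.
    """

    kind: str = "constant"
    p0: float = 6.3
    dph: float = 0.0
    f: float = 1.0
    seed: int = 0
    clamp_lo: float = 5.1
    clamp_hi: float = 7.5
    _switches: np.ndarray = field(default=None, repr=False, compare=False)
    _levels: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid", "telegraph"):
            raise ValueError(f"unknown driver kind {self.kind!r}")
        if self.dph < 0:
            raise ValueError("fluctuation amplitude must be non-negative")
        if self.kind != "constant" and self.f <= 0:
            raise ValueError("fluctuation frequency must be positive")

    # -- constructors -------------------------------------------------
    @classmethod
    def constant(cls, p0: float, **kw) -> "PHDriver":
        return cls(kind="constant", p0=p0, **kw)

    @classmethod
    def sinusoid(cls, p0: float, dph: float, f: float, **kw) -> "PHDriver":
        return cls(kind="sinusoid", p0=p0, dph=dph, f=f, **kw)

    @classmethod
    def telegraph(cls, p0: float, dph: float, f: float, seed: int = 0, **kw) -> "PHDriver":
        drv = cls(kind="telegraph", p0=p0, dph=dph, f=f, seed=seed, **kw)
        drv._init_telegraph()
        return drv

    def _init_telegraph(self) -> None:
        rng = np.random.default_rng(self.seed)
        self._rng = rng
        self._switches = np.array([0.0])
        self._levels = np.array([1.0 if rng.random() < 0.5 else -1.0])

    def _extend_telegraph(self, t: float) -> None:
        while self._switches[-1] <= t:
            hold = self._rng.exponential(1.0 / self.f, size=64)
            new_t = self._switches[-1] + np.cumsum(hold)
            new_lvl = self._levels[-1] * (-1.0) ** np.arange(1, 65)
            self._switches = np.concatenate([self._switches, new_t])
            self._levels = np.concatenate([self._levels, new_lvl])

    # -- evaluation ---------------------------------------------------
    def ph_at(self, t: float) -> float:
        if not math.isfinite(t) or t < 0:
            raise ValueError(f"time must be finite and non-negative, got {t!r}")
        if self.kind == "constant":
            p = self.p0
        elif self.kind == "sinusoid":
            p = self.p0 + self.dph * math.sin(2.0 * math.pi * self.f * t)
        else:
            self._extend_telegraph(t)
            k = np.searchsorted(self._switches, t, side="right") - 1
            p = self.p0 + self.dph * self._levels[k]
        return min(max(p, self.clamp_lo), self.clamp_hi)

    def switch_times(self, t0: float, t1: float) -> np.ndarray:
        """Discontinuity times in (t0, t1); empty for smooth drivers."""
        if self.kind != "telegraph" or self.dph == 0:
            return np.empty(0)
        self._extend_telegraph(t1)
        s = self._switches
        return s[(s > t0) & (s < t1)]


def ph_at(driver: PHDriver, t: float) -> float:
    """Functional alias for :meth:`PHDriver.ph_at`."""
    return driver.ph_at(t)


@dataclass(frozen=True)
class SimulationConfig:
    """Model parameters; defaults follow the standard parameter table."""

    delta: float = 0.1          # dilution rate, 1/h (plausible range 0.03-0.3)
    n_ext: float = 1e-6         # extinction density, OD
    s0: float = 1e-4            # initial density per strain, OD
    n_gen: int = 100            # generations simulated
    n_c: int = 20               # strains per initial assemblage
    n_s: int = 10000            # ensemble instances at full scale
    f_p: float = 0.2            # strain-level parameter variation
    ph_min: float = 5.1
    ph_max: float = 7.5
    f_ph: float = 1.0           # default sinusoid frequency, 1/h
    dph: float = 0.5            # default sinusoid amplitude
    p0: float = 6.3             # default fluctuation midpoint
    rel_tol: float = 1e-7
    abs_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("dilution rate must be positive")
        if not self.n_ext < self.s0:
            raise ValueError("extinction threshold must be below initial density")
        if self.ph_min >= self.ph_max:
            raise ValueError("pH range must be non-empty")

    @property
    def generation_time(self) -> float:
        """Hours per generation: population turnover time ln(2)/delta."""
        return math.log(2.0) / self.delta

    @property
    def total_time(self) -> float:
        return self.n_gen * self.generation_time

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Sampled densities over time plus the pH trace."""

    times: np.ndarray            # (t,)
    densities: np.ndarray        # (n_strains, t)
    ph: np.ndarray               # (t,)
    strain_ids: list[str] = field(default_factory=list)

    @property
    def final(self) -> np.ndarray:
        return self.densities[:, -1]

    def at_time(self, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.times - t)))
        return self.densities[:, k]

    def window(self, t0: float) -> "Trajectory":
        m = self.times >= t0 - 1e-9
        return Trajectory(self.times[m], self.densities[:, m], self.ph[m],
                          self.strain_ids)

    def to_frame(self) -> pd.DataFrame:
        ids = self.strain_ids or [str(i) for i in range(self.densities.shape[0])]
        rows = []
        for i, sid in enumerate(ids):
            rows.append(pd.DataFrame({
                "time": self.times, "strain_id": sid,
                "density": self.densities[i], "ph": self.ph,
            }))
        return pd.concat(rows, ignore_index=True)


def glv_rhs(
    state: np.ndarray, p: float, community: Community, config: SimulationConfig
) -> np.ndarray:
    """Per-strain growth derivative at pH ``p`` (OD/h).

    Reference implementation; :func:`simulate` uses an equivalent
    pre-compiled closure.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("densities must be finite")
    g = community.grid.values
    r = np.array([np.interp(p, g, s.response.r) for s in community.strains])
    K = np.array([np.interp(p, g, s.response.K) for s in community.strains])
    c = community.interactions.at_ph(p)
    s_pos = np.maximum(state, 0.0)
    return s_pos * (r * (1.0 + (c @ s_pos) / K) - config.delta)


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _glv_kernel(S, p, g0, dg0, m, r_tab, k_tab, c, delta):  # pragma: no cover
        n = S.shape[0]
        x = (p - g0) / dg0
        if x < 0.0:
            x = 0.0
        elif x > m - 1.0:
            x = m - 1.0
        i = int(x)
        if i > m - 2:
            i = m - 2
        frac = x - float(i)
        sc = np.empty(n)
        for a in range(n):
            sc[a] = S[a] if S[a] > 0.0 else 0.0
        out = np.empty(n)
        for a in range(n):
            r = r_tab[i, a] + frac * (r_tab[i + 1, a] - r_tab[i, a])
            K = k_tab[i, a] + frac * (k_tab[i + 1, a] - k_tab[i, a])
            gam = 0.0
            for b in range(n):
                gam += c[a, b] * sc[b]
            out[a] = sc[a] * (r * (1.0 + gam / K) - delta)
        return out


def _make_ph_func(driver: PHDriver):
    """Fast scalar time->pH closure matching driver.ph_at."""
    lo, hi = driver.clamp_lo, driver.clamp_hi
    if driver.kind == "constant":
        p_const = min(max(driver.p0, lo), hi)
        return lambda t: p_const
    if driver.kind == "sinusoid":
        p0, dph, w = driver.p0, driver.dph, 2.0 * math.pi * driver.f

        def ph(t):
            p = p0 + dph * math.sin(w * t)
            return lo if p < lo else (hi if p > hi else p)

        return ph
    return driver.ph_at


def _make_rhs(community: Community, driver: PHDriver, config: SimulationConfig):
    grid = community.grid.values
    g0, g1 = grid[0], grid[-1]
    m = len(grid)
    dg = np.diff(grid)
    uniform = np.allclose(dg, dg[0])
    dg0 = dg[0]
    r_tab = np.ascontiguousarray(community.r_table().T)  # (g, n)
    k_tab = np.ascontiguousarray(community.k_table().T)
    C = community.interactions
    c_base = C.c
    slopes = C.slopes
    p0c = C.p0
    delta = config.delta
    ph_at_t = _make_ph_func(driver)

    if _HAVE_NUMBA and uniform and slopes is None:
        c_contig = np.ascontiguousarray(c_base)

        def rhs_fast(t, S):
            return _glv_kernel(S, ph_at_t(t), g0, dg0, m, r_tab,
                               k_tab, c_contig, delta)

        return rhs_fast

    def rhs(t, S):
        p = ph_at_t(t)
        if p <= g0:
            r, K = r_tab[0], k_tab[0]
        elif p >= g1:
            r, K = r_tab[-1], k_tab[-1]
        else:
            if uniform:
                x = (p - g0) / dg0
                i = min(int(x), m - 2)
                frac = x - i
            else:
                i = int(np.searchsorted(grid, p)) - 1
                frac = (p - grid[i]) / dg[i]
            r = r_tab[i] + frac * (r_tab[i + 1] - r_tab[i])
            K = k_tab[i] + frac * (k_tab[i + 1] - k_tab[i])
        c = c_base if slopes is None else c_base + slopes * (p - p0c)
        s_pos = np.maximum(S, 0.0)
        return s_pos * (r * (1.0 + (c @ s_pos) / K) - delta)

    return rhs


def simulate(
    community: Community,
    driver: PHDriver,
    config: SimulationConfig,
    T: float | None = None,
    dense_window: float | None = None,
    dense_points: int = 129,
    apply_extinction: bool = True,
) -> Trajectory:
    """Integrate the community under the pH driver.

    Integration proceeds in generation-length chunks (one generation is
    ln(2)/delta hours); at every generation boundary strains below the
    extinction threshold are permanently set to zero.  Densities are
    recorded at each generation boundary and, if ``dense_window`` is
    given, additionally at ``dense_points`` evenly spaced times over the
    final ``dense_window`` hours (for cycle averaging).
    """
    if T is None:
        T = config.total_time
    if T <= 0:
        raise ValueError("simulation horizon must be positive")
    n = community.n
    S = community.densities.astype(float).copy()
    max_k = float(community.k_table().max())
    runaway_at = RUNAWAY_FACTOR * max_k

    gen = config.generation_time
    n_chunks = max(1, int(math.ceil(T / gen - 1e-9)))
    boundaries = np.minimum(np.arange(1, n_chunks + 1) * gen, T)
    boundaries[-1] = T

    sample_times = [np.array([0.0]), boundaries]
    if dense_window is not None:
        w0 = max(T - dense_window, 0.0)
        sample_times.append(np.linspace(w0, T, dense_points))
    t_samples = np.unique(np.concatenate(sample_times))
    # guard against duplicates within float noise
    keep = np.concatenate([[True], np.diff(t_samples) > 1e-12])
    t_samples = t_samples[keep]

    rhs = _make_rhs(community, driver, config)
    out = np.empty((n, len(t_samples)))
    ph_trace = np.empty(len(t_samples))
    out[:, 0] = S
    ph_trace[0] = driver.ph_at(0.0)

    if not np.any(S > 0):
        for k in range(1, len(t_samples)):
            out[:, k] = 0.0
            ph_trace[k] = driver.ph_at(t_samples[k])
        return Trajectory(t_samples, out, ph_trace, community.ids)

    solver = ode(rhs)
    solver.set_integrator(
        "lsoda", rtol=config.rel_tol, atol=config.abs_tol, nsteps=50_000
    )
    solver.set_initial_value(S, 0.0)

    def _check(ok: bool, t: float) -> None:
        if ok:
            return
        y = np.asarray(solver.y)
        if np.any(~np.isfinite(y)) or y.max(initial=0.0) > 0.5 * runaway_at:
            raise RunawayGrowthError(
                "densities diverged during integration; check for mutual "
                "facilitation with c_ij * c_ji > 1"
            )
        raise RuntimeError(f"ODE solver failed near t={t:.3f} h")

    b_idx = 0  # next generation boundary to process
    t_prev = 0.0
    for k in range(1, len(t_samples)):
        t_next = t_samples[k]
        # break at telegraph switch times inside the interval
        for ts in driver.switch_times(t_prev, t_next):
            solver.integrate(ts)
            _check(solver.successful(), ts)
            solver.set_initial_value(np.maximum(solver.y, 0.0), ts)
        solver.integrate(t_next)
        _check(solver.successful(), t_next)
        S = np.maximum(solver.y, 0.0)
        if not np.all(np.isfinite(S)) or S.max(initial=0.0) > runaway_at:
            raise RunawayGrowthError(
                "densities diverged; check for mutual facilitation with "
                "c_ij * c_ji > 1"
            )
        restart = False
        while b_idx < len(boundaries) and t_next >= boundaries[b_idx] - 1e-9:
            if apply_extinction:
                dead = (S < config.n_ext) & (S > 0.0)
                if np.any(dead):
                    S[dead] = 0.0
                    restart = True
            b_idx += 1
        if restart or np.any(solver.y < 0.0):
            solver.set_initial_value(S, t_next)
        out[:, k] = S
        ph_trace[k] = driver.ph_at(t_next)
        t_prev = t_next
    return Trajectory(t_samples, out, ph_trace, community.ids)
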