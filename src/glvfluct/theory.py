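"""Analytic fast- and slow-fluctuation limits, used as oracles.

Fast limit: for dS/dt = r(t) S with r(t) = r0 + rd*sin(2*pi*f*t), the
first-order asymptotic envelope is exp[-(rd/(2*pi*f)) * cos(2*pi*f*t)],
so the log-amplitude of the forced oscillation decays as 1/f.

Slow limit: the community equilibrates to each instantaneous pH; the
steady state solves the linear system [C] S = b with
b_i = (delta - r_i(p)) * K_i(p) / r_i(p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assembly import StableCommunity
from .dynamics import PHDriver, SimulationConfig, simulate
from .strain_panel import InteractionMatrix, PHResponse, interp_response

__all__ = [
    "WKBInput",
    "QuasiStaticSystem",
    "wkb_envelope",
    "quasi_static_composition",
    "quasi_static_delta",
    "verify_limits",
]


@dataclass(frozen=True)
class WKBInput:
    """Sinusoidally forced growth rate: r(t) = r0 + rd*sin(2*pi*f*t)."""

    r0: float
    rd: float
    f: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("frequency must be positive")
        if self.rd < 0:
            raise ValueError("oscillation amplitude must be non-negative")

    @property
    def peak_log_amplitude(self) -> float:
        return self.rd / (2.0 * math.pi * self.f)


@dataclass
class QuasiStaticSystem:
    """Inputs of the slow-limit linear solve."""

    C: InteractionMatrix
    responses: list[PHResponse]
    delta: float

    def __post_init__(self) -> None:
        if len(self.responses) != self.C.n:
            raise ValueError("one pH response per matrix row required")
        if self.delta < 0:
            raise ValueError("dilution rate must be non-negative")

    def condition_number(self, p: float | None = None) -> float:
        c = self.C.c if p is None else self.C.at_ph(p)
        return float(np.linalg.cond(c))


def wkb_envelope(inp: WKBInput, t) -> np.ndarray | float:
    """Fast-fluctuation oscillation envelope at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    env = np.exp(-(inp.rd / (2.0 * math.pi * inp.f))
                 * np.cos(2.0 * math.pi * inp.f * t))
    return float(env) if env.ndim == 0 else env


def _b_vector(sys: QuasiStaticSystem, p: float) -> np.ndarray:
    b = np.empty(len(sys.responses))
    for i, resp in enumerate(sys.responses):
        r, K = interp_response(resp, p)
        if r <= 0:
            raise ValueError(f"growth rate must be positive at pH {p} (species {i})")
        b[i] = (sys.delta - r) * K / r
    return b


def quasi_static_composition(
    sys: QuasiStaticSystem, p: float, reduce_negative: bool = False
) -> np.ndarray:
    """Steady densities from the linear solve [C] S = b at pH ``p``.

    The plain solve ignores positivity; negative components are returned
    as-is so callers can check feasibility.  With
    ``reduce_negative=True`` the most negative component is removed and
    the reduced system re-solved iteratively, returning zeros for the
    removed species.
    """
    c = sys.C.at_ph(p)
    cond = np.linalg.cond(c)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"interaction matrix is singular (condition number {cond:.3g})"
        )
    b = _b_vector(sys, p)
    S = np.linalg.solve(c, b)
    if not reduce_negative:
        return S
    support = list(range(len(b)))
    while support:
        sub = np.array(support)
        S_sub = np.linalg.solve(c[np.ix_(sub, sub)], b[sub])
        if np.all(S_sub >= 0):
            full = np.zeros(len(b))
            full[sub] = S_sub
            return full
        # drop the most negative component (species absent at this pH)
        support.remove(int(sub[np.argmin(S_sub)]))
    return np.zeros(len(b))


def quasi_static_delta(
    sys: QuasiStaticSystem, p: float, p_ref: float
) -> np.ndarray:
    """Slow-limit composition shift: [C]^-1 (b(p) - b(p_ref))."""
    c = sys.C.c
    db = _b_vector(sys, p) - _b_vector(sys, p_ref)
    return np.linalg.solve(c, db)


def system_for(sc: StableCommunity, config: SimulationConfig) -> QuasiStaticSystem:
    comm = sc.community
    return QuasiStaticSystem(
        comm.interactions, [s.response for s in comm.strains], config.delta
    )


def verify_limits(
    sc: StableCommunity,
    config: SimulationConfig,
    dph: float = 0.5,
    f_slow: float = 1e-4,
    f_fast=(1.0, 3.0, 10.0, 30.0, 100.0),
    p0: float | None = None,
    bc_tol: float = 0.01,
    slope_tol: float = 0.1,
) -> dict:
    """Check the simulator against both analytic limits.

    (a) slow forcing: the instantaneous composition must track the
    quasi-static linear-solve prediction within ``bc_tol`` Bray-Curtis;
    (b) fast forcing: the log-density oscillation amplitude must fall
    off as 1/f (log-log slope -1 within ``slope_tol``).
    """
    from .fluctuation_experiments import bray_curtis

    p_mid = p0 if p0 is not None else config.p0
    report: dict = {"dph": dph}
    if dph == 0:
        report.update(slow_max_bc=0.0, slow_ok=True, fast_slope=-1.0,
                      fast_ok=True)
        return report

    # slow limit ------------------------------------------------------
    sys = system_for(sc, config)
    comm = sc.as_community()
    drv = PHDriver.sinusoid(p_mid, dph, f_slow, clamp_lo=config.ph_min,
                            clamp_hi=config.ph_max)
    traj = simulate(comm, drv, config)
    checks = []
    for k in range(len(traj.times) // 2, len(traj.times)):
        pred = quasi_static_composition(sys, traj.ph[k], reduce_negative=True)
        obs = traj.densities[:, k]
        if pred.sum() <= 0 or obs.sum() <= 0:
            continue
        checks.append(bray_curtis(obs / obs.sum(), pred / pred.sum()))
    report["slow_max_bc"] = float(np.max(checks)) if checks else float("nan")
    report["slow_ok"] = bool(checks) and report["slow_max_bc"] < bc_tol

    # fast limit ------------------------------------------------------
    amps = []
    # fast forcing settles within a few relaxation times; a short
    # absolute horizon suffices and keeps the solver cost bounded
    T_fast = max(30.0, 5.0 * config.generation_time)
    for f in f_fast:
        drv = PHDriver.sinusoid(p_mid, dph, f, clamp_lo=config.ph_min,
                                clamp_hi=config.ph_max)
        period = 1.0 / f
        traj = simulate(comm, drv, config, T=T_fast,
                        dense_window=2 * period, dense_points=129)
        w = traj.window(T_fast - 2 * period)
        tot = np.log(np.maximum(w.densities.sum(axis=0), 1e-300))
        amps.append(0.5 * (tot.max() - tot.min()))
    slope = float(np.polyfit(np.log(np.asarray(f_fast)), np.log(amps), 1)[0])
    report["fast_frequencies"] = list(f_fast)
    report["fast_amplitudes"] = [float(a) for a in amps]
    report["fast_slope"] = slope
    report["fast_ok"] = abs(slope + 1.0) < slope_tol
    return report
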