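"""Exact event-driven simulation of the five-stage birth-death-mutation process.

Ground truth for the generating-function solvers: the simulator realises the
same continuous-time Markov branching process whose PGFs the ODE solvers
integrate, so survival probabilities, first-malignancy times and clone-size
moments estimated here must agree with the deterministic solutions to
Monte-Carlo error.

Channels: influx of stage-1 cells at rate N·muN; per stage-i cell, symmetric
division at alpha_i, death at beta_i, and asymmetric division at mu_i that
adds one stage-(i+1) cell while keeping the parent.  The stage-4 mutation
channel creates the first persistent malignant cell, which never dies; the
simulation stops there (or at ``t_max``).

Full-lifetime simulations at the biological rates (alpha ≈ beta ≈ 73/y,
N = 1e8) are not tractable event-by-event; oracle comparisons run at
down-scaled parameters with N reduced and muN inflated so the influx N·muN
is preserved, and correspondingly smaller division/death rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hazard import ModelParameters

__all__ = ["Trajectory", "simulate", "first_hit_times"]

_BLOCK = 4096  # uniforms drawn per RNG call inside the event loop


@dataclass(frozen=True)
class Trajectory:
    """One realisation: event log, populations over time, first-hit time tau."""

    times: np.ndarray  # event times, starting at 0
    pops: np.ndarray  # shape (len(times), 4): P1..P4 after each event
    tau: float  # time of first persistent malignant cell; inf if none
    t_max: float
    params: ModelParameters

    def detected(self, t: float) -> bool:
        """Whether the tumour is clinically detectable at age t (lag applied)."""
        return self.tau <= t - self.params.Tlag

    def population_at(self, t: float) -> np.ndarray:
        """P1..P4 at time t (right-continuous step interpolation)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.pops[max(idx, 0)].copy()

    def write_event_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tP1\tP2\tP3\tP4\n")
            for t, row in zip(self.times, self.pops):
                fh.write(f"{t:.6f}\t" + "\t".join(str(int(x)) for x in row) + "\n")


def _run(
    p: ModelParameters,
    t_max: float,
    rng: np.random.Generator,
    max_events: int,
    record: bool,
):
    v = p.v
    a1, a2, a3, a4 = p.alpha
    b1, b2, b3, b4 = p.beta
    m1, m2, m3, m4 = p.mu
    n1 = n2 = n3 = n4 = 0
    t = 0.0
    tau = math.inf
    times = [0.0] if record else None
    pops = [(0, 0, 0, 0)] if record else None
    n_events = 0
    buf = rng.random(_BLOCK)
    ptr = 0
    while True:
        r1 = (a1 + b1 + m1) * n1
        r2 = (a2 + b2 + m2) * n2
        r3 = (a3 + b3 + m3) * n3
        r4 = (a4 + b4 + m4) * n4
        total = v + r1 + r2 + r3 + r4
        if total <= 0.0:
            break
        if ptr >= _BLOCK - 2:
            buf = rng.random(_BLOCK)
            ptr = 0
        u = buf[ptr]
        ptr += 1
        t -= math.log(1.0 - u) / total
        if t >= t_max:
            t = t_max
            break
        n_events += 1
        if n_events > max_events:
            raise RuntimeError(
                f"event budget {max_events} exceeded at t={t:.3f}; "
                "clone sizes are running away for these rates"
            )
        x = buf[ptr] * total
        ptr += 1
        if x < v:
            n1 += 1
        else:
            x -= v
            if x < r1:
                if x < a1 * n1:
                    n1 += 1
                elif x < (a1 + b1) * n1:
                    n1 -= 1
                else:
                    n2 += 1
            elif x < r1 + r2:
                x -= r1
                if x < a2 * n2:
                    n2 += 1
                elif x < (a2 + b2) * n2:
                    n2 -= 1
                else:
                    n3 += 1
            elif x < r1 + r2 + r3:
                x -= r1 + r2
                if x < a3 * n3:
                    n3 += 1
                elif x < (a3 + b3) * n3:
                    n3 -= 1
                else:
                    n4 += 1
            else:
                x -= r1 + r2 + r3
                if x < a4 * n4:
                    n4 += 1
                elif x < (a4 + b4) * n4:
                    n4 -= 1
                else:
                    tau = t  # first persistent malignant cell
        if record:
            times.append(t)
            pops.append((n1, n2, n3, n4))
        if tau < math.inf:
            break
    return times, pops, tau, t


def simulate(
    p: ModelParameters,
    t_max: float,
    seed: int | np.random.Generator,
    max_events: int = 2_000_000,
) -> Trajectory:
    """One Gillespie realisation up to ``t_max`` or the first malignant cell.

    Reproducible: the same seed yields the same trajectory.  Raises if the
    event count exceeds ``max_events`` (guards runaway clone growth).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not all(math.isfinite(x) for x in (p.v, *p.alpha, *p.beta, *p.mu)):
        raise ValueError("all rates must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times, pops, tau, _ = _run(p, t_max, rng, max_events, record=True)
    return Trajectory(
        times=np.asarray(times),
        pops=np.asarray(pops, dtype=np.int64),
        tau=tau,
        t_max=t_max,
        params=p,
    )


def first_hit_times(
    p: ModelParameters,
    reps: int,
    seed: int | np.random.Generator,
    t_max: float = 100.0,
    max_events: int = 2_000_000,
) -> np.ndarray:
    """i.i.d. sample of tau, the first-malignant-cell time (inf if > t_max).

    The empirical CDF of the sample estimates 1 − S(t) on [0, t_max] (before
    the detection lag), comparable against the PGF survival.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taus = np.empty(reps)
    for i in range(reps):
        _, _, tau, _ = _run(p, t_max, rng, max_events, record=False)
        taus[i] = tau
    return taus
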