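"""Survival, hazard and clone-size computations for the five-stage model.

The model tracks four premalignant compartments P1..P4 (cells carrying 1..4
of the five hits) fed by a normal stem-cell pool of size N.  Normal cells
mutate into stage 1 at rate muN per cell per year; a stage-i cell divides at
rate alpha_i, dies at rate beta_i, and seeds one stage-(i+1) cell by
asymmetric division at rate mu_i without itself changing stage.  The fifth
hit (rate mu4 per stage-4 cell) creates a persistent malignant cell that
never dies; clinical detection follows its first appearance after a fixed
lag of ``Tlag`` years.

Two hazard solvers are provided.  The *approximate* hazard,

    h(t) ≈ mu4 · E[P4(t − Tlag)],

uses only the expected clone sizes (linear ODE cascade; closed-form residue
expansion when the net growth rates are distinct and nonzero) and is valid
while the probability of a malignant cell is small.  The *exact* hazard
solves the Kolmogorov backward equations for the probability generating
functions Phi_i(t) of the branching process evaluated at the point that
marks "no malignant cell yet" (all clone-size arguments 1, malignant
argument 0):

    dPhi_i/dt = alpha_i Phi_i^2 − (alpha_i + beta_i + mu_i) Phi_i
                + mu_i Phi_i Phi_{i+1} + beta_i ,        Phi_5 ≡ 0,
    Phi_i(0) = 1,

integrated by fixed-step fourth-order Runge-Kutta.  Survival then follows
the filtered-Poisson form S(t) = exp{muN·N ∫0^{t−Tlag} (Phi_1 − 1) ds} and

    h(t) = muN · N · (1 − Phi_1(t − Tlag)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .pathways import MutationSequence, completed_states

__all__ = [
    "ModelParameters",
    "PGFState",
    "HazardCurve",
    "CloneExpectation",
    "expected_premalignant",
    "hazard_approx",
    "solve_pgf",
    "hazard_exact",
    "detection_probability",
    "expected_mutant_clones",
    "DEFAULT_RK4_STEP",
    "CONFLUENT_TOL",
]

#: default fixed RK4 step in years; halving changes Phi_1 at t=100 by <1e-8
DEFAULT_RK4_STEP = 1e-2
#: closed-form residue expansion requires all |λi|, |λi − λj| above this
CONFLUENT_TOL = 1e-6


@dataclass(frozen=True)
class ModelParameters:
    """All rates of one five-stage pathway model.

    Units: rates per cell per year; ``N`` a dimensionless cell count;
    ``Tlag`` years.
    """

    N: float
    muN: float
    mu: tuple[float, float, float, float]
    alpha: tuple[float, float, float, float]
    beta: tuple[float, float, float, float]
    Tlag: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu", "alpha", "beta"):
            vals = getattr(self, name)
            if len(vals) != 4:
                raise ValueError(f"{name} must have 4 entries")
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} entries must be non-negative")
        if self.N < 0 or self.muN < 0 or self.Tlag < 0:
            raise ValueError("N, muN and Tlag must be non-negative")
        if any(m >= 1e-2 * (1 + 1e-12) for m in self.mu):
            # the per-cell mutation probability over a lifetime must stay small
            raise ValueError("stage mutation rates must lie below 1e-2 per year")

    @property
    def lam(self) -> tuple[float, float, float, float]:
        """Net growth rates λi = αi − βi."""
        return tuple(a - b for a, b in zip(self.alpha, self.beta))

    @property
    def v(self) -> float:
        """First-hit influx N·muN per year."""
        return self.N * self.muN


@dataclass(frozen=True)
class PGFState:
    """Generating-function values on a time grid at the no-malignancy point."""

    t: np.ndarray
    phi: np.ndarray  # shape (len(t), 4), columns Phi_1..Phi_4
    params: ModelParameters

    @property
    def phi1(self) -> np.ndarray:
        return self.phi[:, 0]

    def survival(self, ages: Sequence[float]) -> np.ndarray:
        """S(age) = exp{muN·N ∫0^{age−Tlag} (Phi_1(s) − 1) ds}."""
        ages = np.asarray(ages, dtype=float)
        # cumulative trapezoid of (Phi_1 − 1) on the solver grid
        integrand = self.phi1 - 1.0
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(self.t))]
        )
        shifted = np.clip(ages - self.params.Tlag, 0.0, self.t[-1])
        integral = np.interp(shifted, self.t, cum)
        return np.exp(self.params.v * integral)


@dataclass(frozen=True)
class HazardCurve:
    """Hazard per person-year on an age grid; zero at and below Tlag."""

    ages: np.ndarray
    hazard: np.ndarray

    @property
    def incidence_per_100k(self) -> np.ndarray:
        return self.hazard * 1e5


@dataclass(frozen=True)
class CloneExpectation:
    """Expected premalignant clone sizes E[P1..P4](t), optionally labelled."""

    ages: np.ndarray
    expected: np.ndarray  # shape (len(ages), 4)
    classes: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# expected clone sizes (linear cascade)
# ---------------------------------------------------------------------------

def _cascade_matrix(p: ModelParameters) -> np.ndarray:
    """Generator of the augmented linear system d/dt (E1..E4, 1)."""
    lam = p.lam
    A = np.zeros((5, 5))
    for i in range(4):
        A[i, i] = lam[i]
    for i in range(1, 4):
        A[i, i - 1] = p.mu[i - 1]
    A[0, 4] = p.v
    return A


def expected_premalignant(p: ModelParameters, t_grid: Sequence[float]) -> CloneExpectation:
    """Expected numbers E[P1..P4](t) of premalignant cells.

    Solves the constant-coefficient cascade dE[Pi]/dt = λi E[Pi] +
    mu_{i−1} E[P_{i−1}] (source muN·N into stage 1) by the matrix exponential
    of the augmented system, which is exact and handles repeated or zero λ
    without special-casing.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1:
        raise ValueError("t_grid must be one-dimensional")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    A = _cascade_matrix(p)
    e0 = np.zeros(5)
    e0[4] = 1.0
    out = np.empty((t.size, 4))
    # propagate between grid points to keep each expm argument small
    order = np.argsort(t)
    state = e0
    prev = 0.0
    results = np.empty((t.size, 5))
    for idx in order:
        dt = t[idx] - prev
        if dt > 0:
            state = expm(A * dt) @ state
            prev = t[idx]
        results[idx] = state
    out = results[:, :4]
    out[np.abs(out) < 1e-300] = 0.0
    return CloneExpectation(ages=t, expected=out)


def _e4_residue(p: ModelParameters, t: np.ndarray) -> np.ndarray:
    """Closed-form E[P4](t) for distinct nonzero λ (Laplace residue sum)."""
    lam = np.asarray(p.lam)
    pref = p.v * p.mu[0] * p.mu[1] * p.mu[2]
    total = np.full_like(t, 1.0 / np.prod(lam), dtype=float)
    for i in range(4):
        denom = lam[i] * np.prod([lam[i] - lam[j] for j in range(4) if j != i])
        total += np.exp(lam[i] * t) / denom
    return pref * total


def _lambda_distinct(p: ModelParameters, tol: float = CONFLUENT_TOL) -> bool:
    lam = p.lam
    if any(abs(l) <= tol for l in lam):
        return False
    return all(
        abs(lam[i] - lam[j]) > tol for i in range(4) for j in range(i + 1, 4)
    )


def hazard_approx(
    p: ModelParameters,
    t_grid: Sequence[float],
    method: str = "auto",
) -> HazardCurve:
    """Approximate hazard h(t) = mu4 · E[P4(t − Tlag)] (zero for t ≤ Tlag).

    ``method``: 'closed' forces the distinct-λ residue form (raises when any
    λ is zero or two λ are within ``CONFLUENT_TOL``); 'cascade' forces the
    matrix-exponential path (confluent-safe); 'auto' picks 'closed' when
    legal.  The two paths agree to high relative accuracy where both apply.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t_grid must be one-dimensional and increasing")
    if method not in ("auto", "closed", "cascade"):
        raise ValueError(f"unknown method {method!r}")
    distinct = _lambda_distinct(p)
    if method == "closed" and not distinct:
        raise ValueError(
            "closed-form path needs distinct nonzero net growth rates; "
            "use the cascade path for confluent cases"
        )
    use_closed = method == "closed" or (method == "auto" and distinct)
    shifted = t - p.Tlag
    pos = shifted > 0
    h = np.zeros_like(t)
    if np.any(pos):
        if use_closed:
            e4 = _e4_residue(p, shifted[pos])
        else:
            e4 = expected_premalignant(p, shifted[pos]).expected[:, 3]
        h[pos] = p.mu[3] * e4
    return HazardCurve(ages=t, hazard=h)


# ---------------------------------------------------------------------------
# exact solution via Kolmogorov backward PGF equations
# ---------------------------------------------------------------------------

def _phi_rhs(phi: np.ndarray, alpha: np.ndarray, beta: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Backward-equation right-hand side; phi has stage as last axis.

    The chain is closed by Phi_5 ≡ 0: the malignant argument is evaluated
    at 0, so the stage-4 transformation channel contributes no product term.
    """
    nxt = np.concatenate([phi[..., 1:], np.zeros_like(phi[..., :1])], axis=-1)
    return alpha * phi**2 - (alpha + beta + mu) * phi + mu * phi * nxt + beta


def _integrate_phi(
    alpha: np.ndarray,
    beta: np.ndarray,
    mu: np.ndarray,
    t_max: float,
    step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 for the Phi system; supports a leading batch axis on mu.

    Returns (t, phi) with phi shaped (n_steps+1, ..., 4).
    """
    n = max(1, int(np.ceil(t_max / step - 1e-9)))
    t = np.linspace(0.0, n * step, n + 1)
    h = step
    phi0 = np.ones(np.broadcast_shapes(alpha.shape, mu.shape))
    out = np.empty((n + 1,) + phi0.shape)
    out[0] = phi0
    phi = phi0
    for k in range(n):
        k1 = _phi_rhs(phi, alpha, beta, mu)
        k2 = _phi_rhs(phi + 0.5 * h * k1, alpha, beta, mu)
        k3 = _phi_rhs(phi + 0.5 * h * k2, alpha, beta, mu)
        k4 = _phi_rhs(phi + h * k3, alpha, beta, mu)
        phi = phi + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = phi
    return t, out


def phi1_at_ages(
    alpha: np.ndarray,
    beta: np.ndarray,
    mu: np.ndarray,
    ages: np.ndarray,
    step: float = DEFAULT_RK4_STEP,
    tol: float = 1e-6,
) -> np.ndarray:
    """Phi_1 at the given ages for a batch of stage-mutation-rate vectors.

    ``mu`` may carry a leading batch axis (B, 4); ``alpha`` and ``beta`` are
    shared across the batch.  Memory stays O(B) by integrating in place and
    sampling Phi_1 at the grid points nearest each age.  Used by the ABC
    fitter, where hundreds of candidate rate vectors share one growth-rate
    pattern.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    mu = np.asarray(mu, dtype=float)
    idx = np.rint(ages / step).astype(int)
    n = int(idx.max(initial=0))
    phi = np.ones(np.broadcast_shapes(alpha.shape, mu.shape))
    shape = (ages.size,) + phi.shape[:-1]
    out = np.empty(shape)
    want = {}
    for j, k in enumerate(idx):
        want.setdefault(int(k), []).append(j)
    for j in want.get(0, []):
        out[j] = 1.0
    h = step
    for k in range(1, n + 1):
        k1 = _phi_rhs(phi, alpha, beta, mu)
        k2 = _phi_rhs(phi + 0.5 * h * k1, alpha, beta, mu)
        k3 = _phi_rhs(phi + 0.5 * h * k2, alpha, beta, mu)
        k4 = _phi_rhs(phi + h * k3, alpha, beta, mu)
        phi = phi + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if k in want:
            if phi.min() < -tol or phi.max() > 1.0 + tol:
                raise RuntimeError("PGF values left [0,1]; reduce the RK4 step")
            for j in want[k]:
                out[j] = np.clip(phi[..., 0], 0.0, 1.0)
    return out


def solve_pgf(
    p: ModelParameters,
    t_max: float,
    step: float = DEFAULT_RK4_STEP,
    tol: float = 1e-6,
) -> PGFState:
    """Integrate the backward PGF equations to ``t_max`` by fixed-step RK4.

    The process is time-homogeneous, so the Phi_i are propagated forward in
    elapsed time from Phi_i(0) = 1.  Raises if any Phi leaves [0, 1] by more
    than ``tol`` (a sign of an unstable step for the given rates).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    alpha = np.asarray(p.alpha, dtype=float)
    beta = np.asarray(p.beta, dtype=float)
    mu = np.asarray(p.mu, dtype=float)
    t, phi = _integrate_phi(alpha, beta, mu, t_max, step)
    if phi.min() < -tol or phi.max() > 1.0 + tol:
        raise RuntimeError(
            f"PGF values left [0,1] (range [{phi.min():.3g}, {phi.max():.3g}]); "
            "reduce the RK4 step"
        )
    phi = np.clip(phi, 0.0, 1.0)
    return PGFState(t=t, phi=phi, params=p)


def hazard_exact(
    p: ModelParameters,
    t_grid: Sequence[float],
    step: float = DEFAULT_RK4_STEP,
) -> HazardCurve:
    """Exact hazard h(t) = muN·N·(1 − Phi_1(t − Tlag)), zero for t ≤ Tlag."""
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t_grid must be one-dimensional and increasing")
    horizon = float(np.max(t)) - p.Tlag
    h = np.zeros_like(t)
    if horizon > 0:
        state = solve_pgf(p, horizon, step=step)
        shifted = t - p.Tlag
        pos = shifted > 0
        phi1 = np.interp(shifted[pos], state.t, state.phi1)
        h[pos] = p.v * (1.0 - phi1)
    return HazardCurve(ages=t, hazard=h)


def detection_probability(
    p: ModelParameters,
    t: float,
    method: str = "exact",
    step: float = DEFAULT_RK4_STEP,
) -> float:
    """Probability that a tumour is clinically detected by age ``t``.

    ``method='exact'`` returns 1 − S(t) from the PGF survival;
    ``method='approx'`` returns 1 − exp{−mu4 ∫0^{t−Tlag} E[P4(s)] ds}.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    horizon = t - p.Tlag
    if horizon <= 0:
        return 0.0
    if method == "exact":
        state = solve_pgf(p, horizon, step=step)
        return float(1.0 - state.survival([t])[0])
    if method == "approx":
        s_grid = np.linspace(0.0, horizon, 513)
        e4 = expected_premalignant(p, s_grid).expected[:, 3]
        integral = np.trapezoid(e4, s_grid)
        return float(1.0 - np.exp(-p.mu[3] * integral))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# labelled clone-size classes
# ---------------------------------------------------------------------------

#: genotype classes plotted against age; keys are frozen completed-alteration
#: sets of a premalignant stage
_CLONE_CLASS_BY_STATE = {
    frozenset({"KRAS+"}): "KRAS+",
    frozenset({"APC-/-"}): "APC-/-",
    frozenset({"KRAS+", "APC-/-"}): "KRAS+ & APC-/-",
    frozenset({"APC-/-", "TP53-/-"}): "APC-/- & TP53-/-",
}


def expected_mutant_clones(
    seq: MutationSequence,
    p: ModelParameters,
    t_grid: Sequence[float],
) -> CloneExpectation:
    """Expected clone sizes aggregated into genotype classes for ``seq``.

    Each premalignant stage is labelled by its completed driver alterations
    (heterozygous-only stages carry no label and contribute to no class);
    stages sharing a class are summed.  Raises when a stage completes a
    combination outside the recognised single-/double-mutant classes
    (e.g. TP53−/− alone), which does not occur along the incidence-supported
    gene orders.
    """
    clones = expected_premalignant(p, t_grid)
    states = completed_states(seq)
    classes: dict[str, np.ndarray] = {}
    for i, state in enumerate(states):
        if not state:
            continue  # heterozygous-only stage: no completed alteration
        label = _CLONE_CLASS_BY_STATE.get(state)
        if label is None:
            raise ValueError(
                f"stage {i + 1} of {seq.id} completes {sorted(state)}, "
                "which has no recognised clone class"
            )
        classes[label] = classes.get(label, 0.0) + clones.expected[:, i]
    return CloneExpectation(ages=clones.ages, expected=clones.expected, classes=classes)
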