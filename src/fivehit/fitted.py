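"""Published fitted mutation rates for the eleven incidence-supported pathways.

Each entry gives the posterior median and 95% credible interval of the
five fitted rates for one pathway (or a pair of pathways sharing identical
rate assignments): ``muN`` is the per-normal-cell first-hit rate per year
(the fitted influx divided by N = 1e8) and ``mu1..mu4`` the stage mutation
rates per cell per year.  These values were obtained by fitting the exact
hazard to SEER 1973-2013 age-specific colorectal incidence scaled to the
15% of cases carrying all three driver alterations; they are shipped as
constants because the registry extract itself is not redistributable.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FittedRates", "FITTED", "fitted_for"]


@dataclass(frozen=True)
class FittedRates:
    """Posterior medians and 95% CIs of (muN, mu1..mu4) for one pathway."""

    pathway_ids: tuple[str, ...]
    muN: float
    mu: tuple[float, float, float, float]
    muN_ci: tuple[float, float]
    mu_ci: tuple[tuple[float, float], ...]

    @property
    def v(self) -> float:
        """Fitted first-hit influx N·muN per year, with N = 1e8."""
        return self.muN * 1e8

    @property
    def theta(self) -> tuple[float, float, float, float, float]:
        return (self.v, *self.mu)


FITTED: tuple[FittedRates, ...] = (
    FittedRates(
        pathway_ids=("K,A1,A2,T1,T2",),
        muN=8.93e-9,
        mu=(4.70e-3, 1.99e-3, 6.99e-4, 2.52e-4),
        muN_ci=(8.93e-9, 9.31e-9),
        mu_ci=((3.92e-3, 5.58e-3), (1.43e-3, 2.76e-3), (4.30e-4, 14.09e-4),
               (1.04e-4, 4.23e-3)),
    ),
    FittedRates(
        pathway_ids=("A1,K,A2,T1,T2",),
        muN=9.30e-8,
        mu=(2.60e-3, 1.60e-3, 1.02e-4, 8.12e-4),
        muN_ci=(6.66e-8, 12.49e-8),
        mu_ci=((1.90e-3, 4.10e-3), (1.30e-3, 2.30e-3), (0.46e-4, 2.47e-4),
               (0.16e-3, 2.00e-3)),
    ),
    FittedRates(
        pathway_ids=("K,A1,T1,A2,T2", "K,T1,A1,A2,T2"),
        muN=9.03e-9,
        mu=(5.30e-3, 3.00e-3, 4.20e-3, 1.90e-3),
        muN_ci=(8.63e-9, 9.41e-9),
        mu_ci=((4.70e-3, 6.10e-3), (2.20e-3, 3.90e-3), (2.80e-3, 5.20e-3),
               (0.97e-3, 3.10e-3)),
    ),
    FittedRates(
        pathway_ids=("A1,A2,T1,T2,K",),
        muN=1.23e-7,
        mu=(5.03e-4, 2.94e-4, 7.92e-4, 1.15e-3),
        muN_ci=(0.71e-7, 2.01e-7),
        mu_ci=((3.08e-4, 9.83e-4), (1.37e-4, 6.21e-4), (3.34e-4, 16.12e-4),
               (0.73e-3, 1.97e-3)),
    ),
    FittedRates(
        pathway_ids=("A1,T1,A2,T2,K", "T1,A1,A2,T2,K"),
        muN=3.27e-7,
        mu=(3.61e-3, 2.18e-3, 5.08e-5, 1.45e-3),
        muN_ci=(2.44e-7, 4.33e-7),
        mu_ci=((2.55e-3, 4.75e-3), (1.49e-3, 2.78e-3), (2.87e-5, 11.18e-5),
               (0.43e-3, 5.84e-3)),
    ),
    FittedRates(
        pathway_ids=("A1,A2,K,T1,T2",),
        muN=8.89e-8,
        mu=(7.23e-4, 1.74e-4, 8.64e-4, 9.83e-4),
        muN_ci=(5.73e-8, 14.26e-8),
        mu_ci=((4.42e-4, 11.75e-4), (0.69e-4, 4.20e-4), (2.59e-4, 19.22e-4),
               (3.54e-4, 19.85e-4)),
    ),
    FittedRates(
        pathway_ids=("A1,A2,T1,K,T2",),
        muN=1.21e-7,
        mu=(5.26e-4, 2.91e-4, 7.49e-4, 1.71e-3),
        muN_ci=(0.68e-7, 1.83e-7),
        mu_ci=((3.36e-4, 10.33e-4), (1.47e-4, 5.67e-4), (2.85e-4, 14.53e-4),
               (0.63e-3, 3.22e-3)),
    ),
    FittedRates(
        pathway_ids=("A1,T1,A2,K,T2", "T1,A1,A2,K,T2"),
        muN=2.76e-7,
        mu=(3.42e-3, 2.64e-3, 2.78e-5, 3.14e-3),
        muN_ci=(2.03e-7, 3.89e-7),
        mu_ci=((2.46e-3, 4.29e-3), (1.95e-3, 4.00e-3), (2.02e-5, 4.19e-5),
               (1.61e-3, 5.22e-3)),
    ),
)


def fitted_for(pathway_id: str) -> FittedRates:
    """Fitted rates for one of the eleven supported pathway ids."""
    for entry in FITTED:
        if pathway_id in entry.pathway_ids:
            return entry
    raise KeyError(f"no fitted rates for pathway {pathway_id!r}")
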