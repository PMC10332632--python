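"""Synthetic age-specific incidence series with registry-like structure.

The fitting target of the package is an age-incidence curve (ages 0-84,
rate per 100,000 person-years) of the kind published by cancer registries.
Because no registry extract ships with the package, this module generates
one from the model itself: the exact hazard of a chosen truth parameter set
is converted to a rate per 100,000, optionally divided by the fraction of
cases carrying all three driver alterations (so the series resembles a
*total* colorectal incidence curve of which the model describes a subset),
and optionally degraded with Poisson counting noise given person-years at
risk.  The truth is recorded so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .hazard import ModelParameters, hazard_exact
from .pathways import MutationSequence

__all__ = [
    "IncidenceSeries",
    "SyntheticConfig",
    "generate",
    "read_incidence",
    "write_incidence",
]


@dataclass(frozen=True)
class IncidenceSeries:
    """Ages (years) and incidence per 100,000 person-years."""

    ages: np.ndarray
    rates: np.ndarray
    person_years: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.size != rates.size:
            raise ValueError("ages and rates must have equal length")
        if ages.size == 0:
            raise ValueError("incidence series is empty")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        if self.person_years is not None:
            py = np.asarray(self.person_years, dtype=float)
            object.__setattr__(self, "person_years", py)
            if py.size != ages.size:
                raise ValueError("person_years length mismatch")
            if np.any(py <= 0):
                raise ValueError("person_years must be positive")

    def scaled(self, factor: float) -> "IncidenceSeries":
        return IncidenceSeries(self.ages, self.rates * factor,
                               self.person_years, dict(self.meta))


@dataclass(frozen=True)
class SyntheticConfig:
    """Truth parameters and observation model for one synthetic series.

    ``fraction_triple_mutant`` is the share of registry cases attributable
    to the modelled (triple-driver) route; the generated series is the model
    rate divided by it, so multiplying the series back by the fraction
    recovers the model curve.
    """

    truth: ModelParameters
    pathway: Optional[MutationSequence] = None
    ages: np.ndarray = field(default_factory=lambda: np.arange(85.0))
    person_years: float = 1e5
    noise: str = "none"  # none | poisson
    fraction_triple_mutant: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        if not 0 < self.fraction_triple_mutant <= 1:
            raise ValueError("fraction_triple_mutant must lie in (0, 1]")
        if self.person_years <= 0:
            raise ValueError("person_years must be positive")


def generate(cfg: SyntheticConfig) -> IncidenceSeries:
    """Generate one incidence series from the configured truth.

    The exact (PGF) hazard is evaluated at the configured ages, expressed
    per 100,000 person-years and divided by ``fraction_triple_mutant``.
    With ``noise='poisson'`` each age's case count is drawn as
    Poisson(rate x person_years / 1e5) and converted back to a rate.
    """
    ages = np.asarray(cfg.ages, dtype=float)
    curve = hazard_exact(cfg.truth, ages)
    rates = curve.incidence_per_100k / cfg.fraction_triple_mutant
    py = np.full(ages.size, float(cfg.person_years))
    if cfg.noise == "poisson":
        rng = np.random.default_rng(cfg.seed)
        counts = rng.poisson(rates * py / 1e5)
        rates = counts / py * 1e5
    meta = {
        "seed": cfg.seed,
        "noise": cfg.noise,
        "fraction_triple_mutant": cfg.fraction_triple_mutant,
        "truth_v": cfg.truth.v,
        "truth_mu": list(cfg.truth.mu),
        "truth_Tlag": cfg.truth.Tlag,
    }
    if cfg.pathway is not None:
        meta["pathway"] = cfg.pathway.id
    return IncidenceSeries(ages=ages, rates=rates, person_years=py, meta=meta)


def write_incidence(series: IncidenceSeries, path) -> None:
    """Write a series as tab-separated text with '#' metadata headers."""
    with open(path, "w") as fh:
        for key, val in series.meta.items():
            fh.write(f"# {key} = {val}\n")
        cols = ["age", "rate_per_100k"]
        if series.person_years is not None:
            cols.append("person_years")
        fh.write("\t".join(cols) + "\n")
        for i in range(series.ages.size):
            row = [f"{series.ages[i]:g}", f"{series.rates[i]:.10g}"]
            if series.person_years is not None:
                row.append(f"{series.person_years[i]:g}")
            fh.write("\t".join(row) + "\n")


def read_incidence(path) -> IncidenceSeries:
    """Read a delimited incidence file (age, rate_per_100k[, person_years]).

    Malformed or negative rows raise with the offending line number.
    """
    meta: dict = {}
    ages, rates, pys = [], [], []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.replace(",", "\t").split()
            if not header_seen:
                header_seen = True
                if not fields[0].lstrip("-").replace(".", "").isdigit():
                    continue  # column-name header
            try:
                values = [float(x) for x in fields]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed row {line!r}") from exc
            if len(values) < 2:
                raise ValueError(f"line {lineno}: need at least age and rate")
            if values[1] < 0:
                raise ValueError(f"line {lineno}: negative rate {values[1]}")
            ages.append(values[0])
            rates.append(values[1])
            if len(values) > 2:
                pys.append(values[2])
    if not ages:
        raise ValueError(f"{path}: no data rows")
    person_years = np.asarray(pys) if len(pys) == len(ages) else None
    return IncidenceSeries(
        ages=np.asarray(ages), rates=np.asarray(rates),
        person_years=person_years, meta=meta,
    )
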