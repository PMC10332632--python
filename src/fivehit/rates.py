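"""Growth- and death-rate assignment for premalignant stages.

Colonic stem cells divide on average every five days, i.e. 365/5 = 73 times
per year.  A stage's growth advantage is additive over completed driver
alterations and is conferred only by KRAS activation (+0.07/y net, via the
division rate) and complete APC inactivation (+0.2/y net, via the death
rate); heterozygous TSG hits and complete TP53 inactivation change nothing.
That yields four rate regimes:

    baseline (incl. TP53-/- alone)   alpha = 73,    beta = 73    (λ = 0)
    KRAS+ (± TP53-/-)                alpha = 73.07, beta = 73    (λ = 0.07)
    APC-/- (± TP53-/-)               alpha = 73,    beta = 72.8  (λ = 0.2)
    APC-/- and KRAS+                 alpha = 73.07, beta = 72.8  (λ = 0.27)
"""

from __future__ import annotations

from dataclasses import dataclass

from .hazard import ModelParameters
from .pathways import MutationSequence, completed_states

__all__ = [
    "BASELINE_DIVISION_RATE",
    "KRAS_NET_GROWTH",
    "APC_NET_GROWTH",
    "APC_DRIVER_POSITIONS",
    "PER_BASE_MUTATION_RATE",
    "apc_point_mutation_rate",
    "StageRates",
    "AlterationState",
    "stage_rates",
    "stage_rates_for_sequence",
    "build_model_parameters",
    "write_rates_table",
]

#: stem-cell divisions per year: one division every five days
BASELINE_DIVISION_RATE = 365 / 5
#: net growth advantage of KRAS-activated clones, per year
KRAS_NET_GROWTH = 0.07
#: net growth advantage of APC-inactivated clones, per year
APC_NET_GROWTH = 0.2

#: number of driver positions in APC and the per-base-pair point mutation
#: rate per year; their product is the expected point-mutation route rate,
#: the benchmark against which fitted APC rates indicate genetic instability
APC_DRIVER_POSITIONS = 604
PER_BASE_MUTATION_RATE = 1.25e-8


def apc_point_mutation_rate(
    n_driver_positions: int = APC_DRIVER_POSITIONS,
    per_bp_rate: float = PER_BASE_MUTATION_RATE,
) -> float:
    """Expected APC driver mutation rate via point mutation alone, per year."""
    return n_driver_positions * per_bp_rate


@dataclass(frozen=True)
class StageRates:
    """Per-cell growth (alpha), death (beta) and net growth (lam) per year."""

    alpha: float
    beta: float

    @property
    def lam(self) -> float:
        return self.alpha - self.beta


@dataclass(frozen=True)
class AlterationState:
    """Genotype of a premalignant stage: completed alterations + het flags."""

    kras: bool = False
    apc_full: bool = False
    tp53_full: bool = False
    apc_het: bool = False
    tp53_het: bool = False

    def __post_init__(self) -> None:
        # a completed TSG implies its first allele was hit earlier
        if self.apc_full and self.apc_het:
            raise ValueError("APC cannot be both heterozygous and fully inactivated")
        if self.tp53_full and self.tp53_het:
            raise ValueError("TP53 cannot be both heterozygous and fully inactivated")

    @classmethod
    def from_completed(cls, completed: frozenset[str]) -> "AlterationState":
        return cls(
            kras="KRAS+" in completed,
            apc_full="APC-/-" in completed,
            tp53_full="TP53-/-" in completed,
        )


def stage_rates(state: AlterationState) -> StageRates:
    """Growth and death rate of a premalignant stage given its genotype.

    Advantages are additive across genes: KRAS activation raises the
    division rate by 0.07/y, APC inactivation lowers the death rate by
    0.2/y, and nothing else (heterozygous hits, TP53 loss) moves either.
    """
    alpha = BASELINE_DIVISION_RATE + (KRAS_NET_GROWTH if state.kras else 0.0)
    beta = BASELINE_DIVISION_RATE - (APC_NET_GROWTH if state.apc_full else 0.0)
    return StageRates(alpha=alpha, beta=beta)


def stage_rates_for_sequence(seq: MutationSequence) -> list[StageRates]:
    """Rates of the four premalignant stages along ``seq``."""
    return [
        stage_rates(AlterationState.from_completed(s)) for s in completed_states(seq)
    ]


def build_model_parameters(
    seq: MutationSequence,
    theta,
    N: float = 1e8,
    Tlag: float = 5.0,
) -> ModelParameters:
    """Assemble full model parameters for a pathway and fitted rates.

    ``theta`` is a FitParameters-like object with attributes ``v`` (first-hit
    influx N·muN per year) and ``mu`` (the four stage mutation rates), or a
    plain 5-sequence (v, mu1..mu4).  Stage growth/death rates follow from
    the genotype after each hit of ``seq``.
    """
    if hasattr(theta, "v") and hasattr(theta, "mu"):
        v, mu = float(theta.v), tuple(theta.mu)
    else:
        vals = tuple(float(x) for x in theta)
        if len(vals) != 5:
            raise ValueError("theta must supply (v, mu1..mu4)")
        v, mu = vals[0], vals[1:]
    if v <= 0:
        raise ValueError("first-hit influx v must be positive")
    if any(not 0 < m < 1e-2 for m in mu):
        raise ValueError("stage mutation rates must lie in (0, 1e-2) per year")
    per_stage = stage_rates_for_sequence(seq)
    return ModelParameters(
        N=N,
        muN=v / N,
        mu=mu,  # type: ignore[arg-type]
        alpha=tuple(r.alpha for r in per_stage),  # type: ignore[arg-type]
        beta=tuple(r.beta for r in per_stage),  # type: ignore[arg-type]
        Tlag=Tlag,
    )


def write_rates_table(path) -> None:
    """Audit table: per-stage alpha/beta/lambda for all 30 sequences (TSV)."""
    from .pathways import enumerate_sequences

    with open(path, "w") as fh:
        fh.write("id\tstage\talpha\tbeta\tlambda\n")
        for seq in enumerate_sequences():
            for i, r in enumerate(stage_rates_for_sequence(seq), start=1):
                fh.write(f"{seq.id}\t{i}\t{r.alpha}\t{r.beta}\t{r.lam:.6g}\n")
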