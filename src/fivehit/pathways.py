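"""Enumeration and classification of driver-mutation orderings.

Colorectal carcinogenesis through the three major driver genes takes five
hits: activation of the oncogene KRAS (one hit) and biallelic inactivation
of the tumour suppressors APC and TP53 (two ordered hits each).  This module
enumerates every legal ordering of those five hits, classifies each ordering
into a growth-rate case (the pattern of equalities and zeros among the net
growth rates of the four premalignant stages) and into one of the six gene
orders (the order in which the three genes complete their alteration), and
ships the eleven orderings that fit age-specific colorectal incidence as a
documented constant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Gene",
    "AlleleStage",
    "HitEvent",
    "MutationSequence",
    "GrowthCase",
    "GeneOrder",
    "EVENT_IDS",
    "enumerate_sequences",
    "classify_growth_case",
    "gene_order",
    "accepted_pathways",
    "completed_states",
    "write_catalog",
]


class Gene(str, Enum):
    KRAS = "KRAS"
    APC = "APC"
    TP53 = "TP53"


class AlleleStage(str, Enum):
    #: single activating hit of an oncogene
    ACTIVATION = "activation"
    #: first allele of a tumour suppressor (heterozygous, no phenotype)
    FIRST_ALLELE = "first_allele"
    #: second allele of a tumour suppressor (complete inactivation)
    SECOND_ALLELE = "second_allele"


@dataclass(frozen=True)
class HitEvent:
    """One mutational event.

    KRAS admits only ``ACTIVATION``; APC and TP53 only ``FIRST_ALLELE`` /
    ``SECOND_ALLELE``.
    """

    gene: Gene
    allele_stage: AlleleStage

    def __post_init__(self) -> None:
        if self.gene is Gene.KRAS:
            if self.allele_stage is not AlleleStage.ACTIVATION:
                raise ValueError("KRAS is an oncogene: single activating hit only")
        elif self.allele_stage is AlleleStage.ACTIVATION:
            raise ValueError(f"{self.gene.value} is a TSG: allele hits only")

    @property
    def label(self) -> str:
        if self.gene is Gene.KRAS:
            return "K"
        prefix = "A" if self.gene is Gene.APC else "T"
        return prefix + ("1" if self.allele_stage is AlleleStage.FIRST_ALLELE else "2")


#: canonical short labels for the five hits
EVENT_IDS = ("K", "A1", "A2", "T1", "T2")

_EVENT_BY_LABEL = {
    "K": HitEvent(Gene.KRAS, AlleleStage.ACTIVATION),
    "A1": HitEvent(Gene.APC, AlleleStage.FIRST_ALLELE),
    "A2": HitEvent(Gene.APC, AlleleStage.SECOND_ALLELE),
    "T1": HitEvent(Gene.TP53, AlleleStage.FIRST_ALLELE),
    "T2": HitEvent(Gene.TP53, AlleleStage.SECOND_ALLELE),
}


@dataclass(frozen=True)
class MutationSequence:
    """An ordered list of the five hits, e.g. ``K,A1,A2,T1,T2``.

    Invariants: exactly one occurrence of each hit, and for each tumour
    suppressor the first-allele hit precedes the second-allele hit.
    """

    events: tuple[HitEvent, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.events]
        if sorted(labels) != sorted(EVENT_IDS):
            raise ValueError(f"need exactly the five hits {EVENT_IDS}, got {labels}")
        for first, second in (("A1", "A2"), ("T1", "T2")):
            if labels.index(first) > labels.index(second):
                raise ValueError(f"{first} must precede {second} in {labels}")

    @property
    def id(self) -> str:
        return ",".join(e.label for e in self.events)

    @classmethod
    def from_id(cls, seq_id: str) -> "MutationSequence":
        labels = [s.strip() for s in seq_id.split(",")]
        try:
            events = tuple(_EVENT_BY_LABEL[lab] for lab in labels)
        except KeyError as exc:
            raise ValueError(f"unknown hit label in {seq_id!r}") from exc
        return cls(events)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


class GrowthCase(str, Enum):
    """The five patterns of equalities/zeros among net growth rates λp1..λp4."""

    CASE1 = "case1"  # λp2 = λp1 and λp4 = λp3
    CASE2 = "case2"  # λp3 = λp2 = λp1
    CASE3 = "case3"  # λp1 = 0 and λp3 = λp2
    CASE4 = "case4"  # λp1 = 0 and λp4 = λp3
    CASE5 = "case5"  # λp1 = 0 and λp2 = 0

    @property
    def lambda_pattern(self) -> str:
        return {
            GrowthCase.CASE1: "λp2=λp1, λp4=λp3",
            GrowthCase.CASE2: "λp3=λp2=λp1",
            GrowthCase.CASE3: "λp1=0, λp3=λp2",
            GrowthCase.CASE4: "λp1=0, λp4=λp3",
            GrowthCase.CASE5: "λp1=0, λp2=0",
        }[self]


@dataclass(frozen=True)
class GeneOrder:
    """Permutation of the three genes by completion of their alteration.

    KRAS completes at its single hit; a TSG completes at its second allele.
    """

    order: tuple[Gene, Gene, Gene]

    @property
    def id(self) -> str:
        return "-".join(g.value for g in self.order)

    def __str__(self) -> str:  # pragma: no cover
        return self.id


def enumerate_sequences() -> list[MutationSequence]:
    """All legal orderings of the five hits, in lexicographic id order.

    There are 5!/(2!·2!) = 30: each tumour suppressor's two allele hits are
    internally ordered, which halves the 120 raw permutations twice.
    """
    seqs = []
    for perm in itertools.permutations(EVENT_IDS):
        if perm.index("A1") < perm.index("A2") and perm.index("T1") < perm.index("T2"):
            seqs.append(MutationSequence.from_id(",".join(perm)))
    seqs.sort(key=lambda s: s.id)
    return seqs


def completed_states(seq: MutationSequence) -> list[frozenset[str]]:
    """Completed-alteration sets after each of the first four hits.

    Element i is the subset of {"KRAS+", "APC-/-", "TP53-/-"} completed by
    the first i+1 events; the fifth hit creates the malignant cell and has
    no premalignant stage of its own.
    """
    done: set[str] = set()
    states = []
    for event in seq.events[:4]:
        if event.gene is Gene.KRAS:
            done.add("KRAS+")
        elif event.allele_stage is AlleleStage.SECOND_ALLELE:
            done.add(f"{event.gene.value}-/-")
        states.append(frozenset(done))
    return states


def classify_growth_case(seq: MutationSequence) -> GrowthCase:
    """Assign the growth-rate case of a sequence.

    The case is determined by where growth-relevant completions fall: a
    premalignant stage has zero net growth until either KRAS is activated or
    APC is fully inactivated, and consecutive stages share a growth rate
    exactly when the hit between them completes no alteration (a first-allele
    hit).  Tracking the full completed-alteration set (TP53 included)
    reproduces the printed per-case groupings, which the raw λ values alone
    do not determine uniquely.
    """
    if not isinstance(seq, MutationSequence):
        raise TypeError("classify_growth_case expects a MutationSequence")
    s = completed_states(seq)
    if s[0]:  # KRAS first
        if s[2] == s[1] == s[0]:
            return GrowthCase.CASE2
        # remaining K-first interleavings: one TSG fully before the other
        return GrowthCase.CASE1
    if not s[1]:
        return GrowthCase.CASE5
    if s[2] == s[1]:
        return GrowthCase.CASE3
    return GrowthCase.CASE4


def gene_order(seq: MutationSequence) -> GeneOrder:
    """Order of the three genes by the position of their completing hit."""
    labels = [e.label for e in seq.events]
    completion = {
        Gene.KRAS: labels.index("K"),
        Gene.APC: labels.index("A2"),
        Gene.TP53: labels.index("T2"),
    }
    order = tuple(sorted(completion, key=completion.get))
    return GeneOrder(order)  # type: ignore[arg-type]


#: The eleven mutation orderings that fit SEER age-specific colorectal
#: incidence, restricted to the gene orders KRAS-APC-TP53 (4 pathways),
#: APC-TP53-KRAS (3) and APC-KRAS-TP53 (4).  A curated constant, not a
#: computation: selecting them requires the registry extract.
ACCEPTED_PATHWAY_IDS = (
    # KRAS-APC-TP53
    "K,A1,A2,T1,T2",
    "A1,K,A2,T1,T2",
    "K,A1,T1,A2,T2",
    "K,T1,A1,A2,T2",
    # APC-TP53-KRAS
    "A1,A2,T1,T2,K",
    "A1,T1,A2,T2,K",
    "T1,A1,A2,T2,K",
    # APC-KRAS-TP53
    "A1,A2,K,T1,T2",
    "A1,A2,T1,K,T2",
    "A1,T1,A2,K,T2",
    "T1,A1,A2,K,T2",
)


def accepted_pathways() -> list[MutationSequence]:
    """The eleven incidence-supported pathways (see ACCEPTED_PATHWAY_IDS)."""
    return [MutationSequence.from_id(i) for i in ACCEPTED_PATHWAY_IDS]


def write_catalog(path) -> None:
    """Write the 30-row pathway catalog as tab-separated text.

    Columns: sequence id, growth case, gene order, accepted flag.
    """
    accepted = set(ACCEPTED_PATHWAY_IDS)
    with open(path, "w") as fh:
        fh.write("# five-hit mutation pathway catalog\n")
        fh.write("id\tcase\tgene_order\taccepted\n")
        for seq in enumerate_sequences():
            fh.write(
                f"{seq.id}\t{classify_growth_case(seq).value}\t"
                f"{gene_order(seq).id}\t{int(seq.id in accepted)}\n"
            )
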