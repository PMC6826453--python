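"""Mendelian multilocus classification of specimens on a diagnostic panel.

At a diagnostic locus the two species are fixed for alternative alleles, so
first-generation cross classes have fully determined genotype
distributions over (AA, AB, BB), with A the species-A allele:

====================  ==================
class                 (AA, AB, BB)
====================  ==================
PURE_A                (1, 0, 0)
PURE_B                (0, 0, 1)
F1 (A x B)            (0, 1, 0)
F2 (F1 x F1)          (1/4, 1/2, 1/4)
BC_A (F1 x pure A)    (1/2, 1/2, 0)
BC_B (F1 x pure B)    (0, 1/2, 1/2)
====================  ==================

Panel loci are assumed unlinked (the panel's unique-alignment filter
motivates this), so the multilocus likelihood of a specimen under a class
is the product over loci. Classification is maximum a posteriori with a
uniform prior by default. A small genotyping-error probability epsilon
spreads each class's mass symmetrically onto the other two genotypes, so a
single miscall cannot produce a -infinity log-likelihood cliff.

The module also answers the analytic power question behind panel sizing:
the probability that a hybrid class yields a multilocus genotype
indistinguishable from a pure species (for BC this is 0.5^L, for F2
2 * 0.25^L, for F1 zero), and its complement, the detection power.
Later-generation backcrosses converge on the pure classes and are outside
the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import logsumexp

from .genotype_io import SpecimenPanelGenotype

__all__ = [
    "HybridClass",
    "CLASS_ORDER",
    "HYBRID_CLASSES",
    "PURE_CLASSES",
    "class_genotype_probs",
    "HybridClassModel",
    "ClassificationResult",
    "multilocus_loglik",
    "classify_specimen",
    "pure_appearance_prob",
    "detection_power",
    "min_loci_for_confidence",
]


class HybridClass(str, Enum):
    PURE_A = "PURE_A"
    PURE_B = "PURE_B"
    F1 = "F1"
    F2 = "F2"
    BC_A = "BC_A"
    BC_B = "BC_B"


#: fixed order used for deterministic tie-breaking
CLASS_ORDER: tuple[HybridClass, ...] = (
    HybridClass.PURE_A,
    HybridClass.PURE_B,
    HybridClass.F1,
    HybridClass.F2,
    HybridClass.BC_A,
    HybridClass.BC_B,
)
PURE_CLASSES = frozenset({HybridClass.PURE_A, HybridClass.PURE_B})
HYBRID_CLASSES = frozenset({HybridClass.F1, HybridClass.F2, HybridClass.BC_A, HybridClass.BC_B})

_ERROR_FREE: dict[HybridClass, tuple[float, float, float]] = {
    HybridClass.PURE_A: (1.0, 0.0, 0.0),
    HybridClass.PURE_B: (0.0, 0.0, 1.0),
    HybridClass.F1: (0.0, 1.0, 0.0),
    HybridClass.F2: (0.25, 0.5, 0.25),
    HybridClass.BC_A: (0.5, 0.5, 0.0),
    HybridClass.BC_B: (0.0, 0.5, 0.5),
}

#: index of each observable genotype code in a probability triple
GENOTYPE_INDEX = {"AA": 0, "AB": 1, "BB": 2}


def class_genotype_probs(cls: HybridClass, epsilon: float = 0.0) -> np.ndarray:
    """Genotype probability triple (AA, AB, BB) for a class at one
    diagnostic locus, under the symmetric-error model: the observed
    genotype equals the true one with probability 1 - epsilon, otherwise
    it is one of the other two genotypes uniformly."""
    if not (0.0 <= epsilon < 0.5):
        raise ValueError(f"epsilon must be in [0, 0.5), got {epsilon}")
    g = np.array(_ERROR_FREE[cls], dtype=float)
    probs = g * (1.0 - epsilon) + (1.0 - g) * (epsilon / 2.0)
    # renormalise exactly (the symmetric spread preserves the sum already)
    return probs / probs.sum()


@dataclass
class HybridClassModel:
    """Per-class genotype distributions shared across panel loci.

    Diagnostic loci are exchangeable under the Mendelian model, so one
    triple per class suffices; ``epsilon`` is the genotyping-error
    probability (default 0.001).
    """

    epsilon: float = 0.001
    _cache: dict[HybridClass, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError(f"epsilon must be in [0, 0.5), got {self.epsilon}")

    def probs(self, cls: HybridClass) -> np.ndarray:
        if cls not in self._cache:
            self._cache[cls] = class_genotype_probs(cls, self.epsilon)
        return self._cache[cls]


@dataclass
class ClassificationResult:
    specimen_id: str
    log_likelihood: dict[HybridClass, float]
    posterior: dict[HybridClass, float]
    ml_class: HybridClass
    n_loci_used: int
    tie: bool = False

    @property
    def flags(self) -> set[str]:
        out = set()
        if self.ml_class in PURE_CLASSES:
            out.add("PURE_CONSISTENT")
        else:
            out.add("HYBRID_EVIDENCE")
        if self.tie:
            out.add("TIE")
        return out


def multilocus_loglik(
    specimen: SpecimenPanelGenotype, cls: HybridClass, epsilon: float = 0.0
) -> float:
    """Log-likelihood of the specimen's panel genotypes under one class;
    MISSING (NA) loci are skipped. -inf is a legitimate value at
    epsilon = 0 (an impossible genotype under the class)."""
    probs = class_genotype_probs(cls, epsilon)
    ll = 0.0
    n_used = 0
    for code in specimen.genotypes.values():
        if code == "NA":
            continue
        n_used += 1
        p = probs[GENOTYPE_INDEX[code]]
        ll += math.log(p) if p > 0 else -math.inf
    if n_used == 0:
        raise ValueError(
            f"specimen {specimen.specimen_id}: all panel loci are missing"
        )
    return ll


def classify_specimen(
    specimen: SpecimenPanelGenotype,
    model: HybridClassModel | None = None,
    prior: dict[HybridClass, float] | None = None,
) -> ClassificationResult:
    """MAP class assignment with per-class posteriors.

    Posteriors are proportional to prior x likelihood, normalised in log
    space; ties on the posterior are broken by the fixed CLASS_ORDER and
    flagged. The prior defaults to uniform (wild hybrid frequencies are
    generally unknown).
    """
    model = model or HybridClassModel()
    if prior is None:
        prior = {c: 1.0 for c in CLASS_ORDER}
    if any(w < 0 for w in prior.values()) or sum(prior.values()) <= 0:
        raise ValueError("prior weights must be non-negative and not all zero")

    logliks = {
        c: multilocus_loglik(specimen, c, model.epsilon) for c in CLASS_ORDER
    }
    n_used = specimen.n_typed
    logpost = np.array(
        [
            (math.log(prior.get(c, 0.0)) if prior.get(c, 0.0) > 0 else -math.inf)
            + logliks[c]
            for c in CLASS_ORDER
        ]
    )
    norm = logsumexp(logpost)
    post = np.exp(logpost - norm)
    best = float(post.max())
    winners = [c for c, p in zip(CLASS_ORDER, post) if math.isclose(p, best, rel_tol=1e-12, abs_tol=0.0)]
    return ClassificationResult(
        specimen_id=specimen.specimen_id,
        log_likelihood=logliks,
        posterior={c: float(p) for c, p in zip(CLASS_ORDER, post)},
        ml_class=winners[0],
        n_loci_used=n_used,
        tie=len(winners) > 1,
    )


# ---------------------------------------------------------------------------
# analytic power of a panel of L diagnostic loci
# ---------------------------------------------------------------------------


def pure_appearance_prob(cls: HybridClass, n_loci: int) -> float:
    """Probability that the class produces a multilocus genotype identical
    to some pure-species genotype across ``n_loci`` independent diagnostic
    loci (error-free Mendelian segregation).

    BC_A/BC_B: (1/2)^L (all homozygous for the recurrent parent's allele);
    F2: 2 * (1/4)^L (all-AA or all-BB); F1: 0 (always heterozygous);
    pure classes trivially 1.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if cls in PURE_CLASSES:
        return 1.0
    if cls is HybridClass.F1:
        return 0.0
    if cls is HybridClass.F2:
        return 2.0 * 0.25**n_loci
    return 0.5**n_loci  # BC_A or BC_B


def detection_power(cls: HybridClass, n_loci: int) -> float:
    """Probability of flagging the class as non-pure from its multilocus
    genotype: 1 - pure_appearance_prob."""
    return 1.0 - pure_appearance_prob(cls, n_loci)


def min_loci_for_confidence(cls: HybridClass, target: float) -> int:
    """Smallest panel size L with detection_power(cls, L) >= target.

    F1 returns 1 (power is already 1 at a single locus); pure classes are
    rejected because detection power is undefined for them.
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target must be in (0, 1), got {target}")
    if cls in PURE_CLASSES:
        raise ValueError(f"detection power is undefined for pure class {cls.value}")
    if cls is HybridClass.F1:
        return 1
    L = 1
    while detection_power(cls, L) < target:
        L += 1
    return L
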