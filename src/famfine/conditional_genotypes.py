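"""Offspring genotype distributions conditional on the family's sufficient
statistic, with exact moments under additive/recessive/dominant codings.

Family-based association tests condition on the observed phenotypes and on
the sufficient statistic for the parental genotype distribution within each
nuclear family, which removes any dependence on parental allele frequencies
and hence on population structure.  Two cases are handled:

* **Both parents genotyped** — offspring genotypes are independent Mendelian
  transmissions from the parental pair; the conditional distribution is the
  product distribution over offspring.
* **At least one parent missing** — offspring are exchangeable given the
  (unknown) parents, so conditioning on the multiset of observed offspring
  genotypes leaves a uniform distribution over its distinct orderings.  This
  covers the sibship design exactly; for families with exactly one genotyped
  parent it is conservative (the typed parent's information is ignored) but
  remains a valid conditional law.

A family is *informative* for a factor when the conditional distribution of
its coded genotypes is non-degenerate (positive conditional variance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .family_io import MISSING, NuclearFamily

_MODELS = ("additive", "recessive", "dominant")
_ALLELES = ("allele1", "allele2")

#: transmission probability of allele2 given parental dosage
_TRANSMIT = np.array([0.0, 0.5, 1.0])

# _CHILD_DIST[gf, gm, d] = P(child dosage = d | parental dosages gf, gm)
_CHILD_DIST = np.zeros((3, 3, 3))
for _gf in range(3):
    for _gm in range(3):
        _tf, _tm = _TRANSMIT[_gf], _TRANSMIT[_gm]
        _CHILD_DIST[_gf, _gm, 0] = (1 - _tf) * (1 - _tm)
        _CHILD_DIST[_gf, _gm, 1] = _tf * (1 - _tm) + (1 - _tf) * _tm
        _CHILD_DIST[_gf, _gm, 2] = _tf * _tm


class MendelianError(ValueError):
    """Observed offspring genotype impossible given the genotyped parents."""

    def __init__(self, family_id: str, variant_id: str):
        super().__init__(
            f"family {family_id}, variant {variant_id}: offspring genotype "
            "inconsistent with parental genotypes"
        )
        self.family_id = family_id
        self.variant_id = variant_id


@dataclass(frozen=True)
class FactorCoding:
    """A genetic factor: one (variant, inheritance model, coded allele) unit.

    Under the additive model there is one factor per variant (the allele2
    dosage); under recessive/dominant models each allele defines its own
    factor, so a variant contributes two factors.
    """

    variant_id: str
    model: str
    coded_allele: str = "allele2"

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown genetic model {self.model!r}")
        if self.coded_allele not in _ALLELES:
            raise ValueError(f"coded_allele must be one of {_ALLELES}")
        if self.model == "additive" and self.coded_allele != "allele2":
            raise ValueError("additive factors are coded on allele2 dosage")


def coded_values(factor: FactorCoding) -> np.ndarray:
    """Coded genotype value for each allele2 dosage 0/1/2, as a length-3 array."""
    d = np.arange(3)
    da = d if factor.coded_allele == "allele2" else 2 - d
    if factor.model == "additive":
        return da.astype(float)
    if factor.model == "recessive":
        return (da == 2).astype(float)
    return (da >= 1).astype(float)  # dominant


def code_genotype(dosage: int, factor: FactorCoding) -> float:
    """Code a single non-missing allele2 dosage under the factor's model."""
    if dosage == MISSING:
        raise ValueError("cannot code a missing dosage")
    if dosage not in (0, 1, 2):
        raise ValueError(f"invalid dosage {dosage}")
    return float(coded_values(factor)[dosage])


@dataclass
class OffspringConditional:
    """Conditional distribution of the genotyped offspring's dosages.

    ``support`` lists (configuration, probability) pairs, one dosage per
    genotyped offspring in ``offspring_index`` order.  ``informative`` is
    False when the support is a single configuration.
    """

    family_id: str
    variant_id: str
    offspring_index: list[int]
    support: list[tuple[tuple[int, ...], float]]
    informative: bool


@dataclass
class ConditionalMoments:
    """Exact conditional mean and covariance of coded offspring genotypes."""

    family_id: str
    factor: FactorCoding
    offspring_index: list[int]
    mean_vector: np.ndarray
    covariance_matrix: np.ndarray
    informative: bool


def _genotyped(family: NuclearFamily, j: int) -> tuple[list[int], list[int]]:
    idx = [
        i for i, off in enumerate(family.offspring) if off.genotypes[j] != MISSING
    ]
    obs = [int(family.offspring[i].genotypes[j]) for i in idx]
    return idx, obs


def _parent_dosages(family: NuclearFamily, j: int) -> tuple[int, int] | None:
    """Both parents' dosages at variant j, or None if either is unavailable."""
    if family.father_genotypes is None or family.mother_genotypes is None:
        return None
    gf, gm = int(family.father_genotypes[j]), int(family.mother_genotypes[j])
    if gf == MISSING or gm == MISSING:
        return None
    return gf, gm


def offspring_conditional(
    family: NuclearFamily, variant_index: int, variant_id: str | None = None
) -> OffspringConditional:
    """Exact conditional distribution of offspring dosages at one variant.

    With two genotyped parents the support is the product of the per-child
    Mendelian transmission distributions; otherwise it is uniform over the
    distinct orderings of the observed offspring dosage multiset.
    """
    j = variant_index
    vid = variant_id if variant_id is not None else str(j)
    idx, obs = _genotyped(family, j)
    parents = _parent_dosages(family, j)

    if parents is not None:
        gf, gm = parents
        dist = _CHILD_DIST[gf, gm]
        for d in obs:
            if dist[d] <= 0.0:
                raise MendelianError(family.family_id, vid)
        child_support = [d for d in range(3) if dist[d] > 0.0]
        support = []
        for config in itertools.product(child_support, repeat=len(idx)):
            prob = float(np.prod([dist[d] for d in config])) if config else 1.0
            support.append((tuple(config), prob))
    else:
        if len(obs) < 2:
            support = [(tuple(obs), 1.0)]
        else:
            orderings = sorted(set(itertools.permutations(obs)))
            pr = 1.0 / len(orderings)
            support = [(o, pr) for o in orderings]

    return OffspringConditional(
        family_id=family.family_id,
        variant_id=vid,
        offspring_index=idx,
        support=support,
        informative=len(support) > 1,
    )


def moments_from_conditional(
    cond: OffspringConditional, factor: FactorCoding
) -> ConditionalMoments:
    """Moments of the coded configuration by direct enumeration of the support."""
    cv = coded_values(factor)
    n = len(cond.offspring_index)
    mean = np.zeros(n)
    second = np.zeros((n, n))
    for config, prob in cond.support:
        c = cv[list(config)] if n else np.zeros(0)
        mean += prob * c
        second += prob * np.outer(c, c)
    cov = second - np.outer(mean, mean)
    cov = (cov + cov.T) / 2.0
    return ConditionalMoments(
        family_id=cond.family_id,
        factor=factor,
        offspring_index=cond.offspring_index,
        mean_vector=mean,
        covariance_matrix=cov,
        informative=bool(np.any(np.abs(cov) > 1e-12)),
    )


def conditional_moments(
    family: NuclearFamily, factor: FactorCoding, variant_index: int
) -> ConditionalMoments:
    """Exact conditional mean/covariance of coded offspring genotypes.

    Uses closed forms: with two genotyped parents the coded offspring values
    are i.i.d. draws from the coded transmission distribution (diagonal
    covariance); under the permutation law the covariance is the exchangeable
    matrix with ``Var = s²`` and ``Cov = −s²/(n−1)`` where ``s²`` is the
    population variance of the observed coded values (row sums of the coded
    configuration are fixed).
    """
    j = variant_index
    idx, obs = _genotyped(family, j)
    parents = _parent_dosages(family, j)
    cv = coded_values(factor)
    n = len(idx)

    if parents is not None:
        gf, gm = parents
        dist = _CHILD_DIST[gf, gm]
        for d in obs:
            if dist[d] <= 0.0:
                raise MendelianError(family.family_id, factor.variant_id)
        mu = float(dist @ cv)
        var = float(dist @ cv**2) - mu**2
        var = max(var, 0.0)
        mean = np.full(n, mu)
        cov = np.eye(n) * var
    else:
        if n < 2:
            mean = cv[obs].astype(float) if n else np.zeros(0)
            cov = np.zeros((n, n))
        else:
            c = cv[obs]
            mu = float(c.mean())
            s2 = float(np.mean((c - mu) ** 2))
            mean = np.full(n, mu)
            cov = np.full((n, n), -s2 / (n - 1))
            np.fill_diagonal(cov, s2)
    return ConditionalMoments(
        family_id=family.family_id,
        factor=factor,
        offspring_index=idx,
        mean_vector=mean,
        covariance_matrix=cov,
        informative=bool(np.any(np.abs(cov) > 1e-12)),
    )


def dump_conditionals(
    families: Sequence[NuclearFamily], variant_index: int
) -> "list[dict]":
    """Diagnostic flat dump of per-family conditional supports (for debugging)."""
    rows = []
    for fam in families:
        cond = offspring_conditional(fam, variant_index)
        for config, prob in cond.support:
            rows.append(
                {
                    "family_id": fam.family_id,
                    "configuration": "/".join(map(str, config)),
                    "probability": prob,
                    "informative": cond.informative,
                }
            )
    return rows
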