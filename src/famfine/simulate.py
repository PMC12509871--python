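"""Synthetic loci and family samples with truth labels for evaluation.

The generator emulates a single fine-mapping locus: a pool of binary
haplotypes over tens of variants with decaying linkage disequilibrium
(first-order Gaussian-copula autoregression), nuclear families sampled by
random mating with Mendelian transmission and no within-locus recombination,
one or two causal variants acting additively or recessively on a
quantitative trait (linear model with unit normal noise) or a binary trait
(liability threshold), and two study designs: trios (offspring plus both
genotyped parents) and sibling pairs with parental genotypes masked.

Each non-causal factor is labelled a *Proxy* when its squared correlation
with some causal factor is at least 0.8, and *Null* otherwise; causal
factors are *Signal*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .conditional_genotypes import FactorCoding, coded_values
from .family_io import FamilySet, NuclearFamily, Offspring, VariantInfo
from .fbat_score import factor_name, panel_factors

logger = logging.getLogger(__name__)

DEFAULT_EFFECT_SIZE = 0.55  # mean causal |z| ~ 6-8 at 1000 trio families
PROXY_R2 = 0.8
GENOME_WIDE_ALPHA = 5e-8
_MAX_POOL_ATTEMPTS = 100


@dataclass
class LocusModel:
    """Parameters of the synthetic locus."""

    p: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.9
    n_haplotypes: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5 + 1e-12):
            raise ValueError("require 0 < maf_min <= maf_max < 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.p < 1 or self.n_haplotypes < 2:
            raise ValueError("p >= 1 and n_haplotypes >= 2 required")


@dataclass
class HaplotypePool:
    haplotypes: np.ndarray  # (n_haplotypes, p) 0/1, 1 = allele2
    frequencies: np.ndarray  # target allele2 frequency per variant
    locus: LocusModel


@dataclass
class EffectSpec:
    """Causal architecture: 1-2 causal variants, inheritance, trait type."""

    causal_indices: tuple[int, ...] = (0,)
    effect_sizes: Optional[Sequence[float]] = None
    inheritance: str = "additive"
    trait: str = "quantitative"
    ascertainment: str = "random"
    prevalence: float = 0.1

    def __post_init__(self) -> None:
        self.causal_indices = tuple(int(i) for i in self.causal_indices)
        if len(self.causal_indices) not in (1, 2):
            raise ValueError("one or two causal effects are supported")
        if self.inheritance not in ("additive", "recessive"):
            raise ValueError("inheritance must be additive or recessive")
        if self.trait not in ("binary", "quantitative"):
            raise ValueError("trait must be binary or quantitative")
        if self.ascertainment not in ("random", "affected_offspring"):
            raise ValueError("unknown ascertainment scheme")
        if self.ascertainment == "affected_offspring" and self.trait != "binary":
            raise ValueError("affected-offspring ascertainment needs a binary trait")
        if self.effect_sizes is None:
            self.effect_sizes = [DEFAULT_EFFECT_SIZE] * len(self.causal_indices)
        self.effect_sizes = [float(b) for b in self.effect_sizes]
        if len(self.effect_sizes) != len(self.causal_indices):
            raise ValueError("effect_sizes must match causal_indices")


@dataclass
class TruthRecord:
    """Per-factor Signal/Proxy/Null labels for one simulated replicate."""

    factor_names: list[str]
    labels: dict[str, str]
    r2_with_causal: dict[str, float]
    causal_factor_names: list[str]
    causal_variant_indices: tuple[int, ...]
    all_causal_genomewide: Optional[bool] = None


def simulate_haplotype_pool(lm: LocusModel) -> HaplotypePool:
    """Binary haplotypes with block/decaying LD from a first-order Markov
    chain along the locus.

    Variant j carries allele2 with a target frequency drawn from
    ``maf_range`` (frequencies of neighbouring variants co-vary, giving
    block-like structure); conditional transition probabilities are chosen so
    the correlation between adjacent variants' alleles equals ``ld_rho``
    exactly where feasible (clipped for strongly mismatched frequencies), and
    LD decays geometrically with distance.  Deterministic under a fixed
    seed.  Pools where any variant comes out (near-)monomorphic are
    resampled, with an error after 100 attempts.
    """
    rng = np.random.default_rng(lm.seed)
    lo, hi = lm.maf_range
    for attempt in range(_MAX_POOL_ATTEMPTS):
        # frequency profile: smooth AR(1) on a latent scale, uniform marginal
        u = np.empty(lm.p)
        u[0] = rng.standard_normal()
        for j in range(1, lm.p):
            u[j] = lm.ld_rho * u[j - 1] + np.sqrt(
                max(1.0 - lm.ld_rho**2, 1e-12)
            ) * rng.standard_normal()
        freqs = lo + (hi - lo) * norm.cdf(u)

        haps = np.empty((lm.n_haplotypes, lm.p), dtype=np.int8)
        haps[:, 0] = rng.random(lm.n_haplotypes) < freqs[0]
        for j in range(1, lm.p):
            fp, fj = freqs[j - 1], freqs[j]
            sd = np.sqrt(fj * (1.0 - fj))
            # transition probabilities giving corr(x_{j-1}, x_j) = ld_rho:
            # P(1|1) = f_j + ρ·sd·sqrt((1-f_p)/f_p), P(1|0) analogous
            p11 = np.clip(fj + lm.ld_rho * sd * np.sqrt((1 - fp) / fp), 0, 1)
            p10 = np.clip(fj - lm.ld_rho * sd * np.sqrt(fp / (1 - fp)), 0, 1)
            prev = haps[:, j - 1] == 1
            prob = np.where(prev, p11, p10)
            haps[:, j] = rng.random(lm.n_haplotypes) < prob
        emp = haps.mean(axis=0)
        se = np.sqrt(freqs * (1 - freqs) / lm.n_haplotypes)
        ok = np.all(emp > 0) and np.all(emp < 1)
        ok = ok and np.all(emp >= lo - 4 * se) and np.all(emp <= hi + 4 * se)
        if ok:
            return HaplotypePool(haps, freqs, lm)
        logger.warning("haplotype pool attempt %d infeasible; resampling", attempt + 1)
    raise RuntimeError(
        "could not generate a feasible haplotype pool after "
        f"{_MAX_POOL_ATTEMPTS} attempts (maf_range={lm.maf_range}, "
        f"ld_rho={lm.ld_rho})"
    )


def _variant_panel(p: int) -> list[VariantInfo]:
    return [
        VariantInfo(f"v{j + 1}", "1", 1 + 1000 * j, "A", "B") for j in range(p)
    ]


def _coded_causal(G: np.ndarray, eff: EffectSpec) -> np.ndarray:
    """Coded causal genotypes (n, n_causal) from dosage matrix columns."""
    X = G[:, list(eff.causal_indices)].astype(float)
    if eff.inheritance == "recessive":
        X = (X == 2).astype(float)
    return X


def _liability_threshold(pool: HaplotypePool, eff: EffectSpec, seed: int) -> float:
    """Threshold giving the target prevalence under random mating, estimated
    once from a large reference batch of offspring liabilities."""
    rng = np.random.default_rng(seed)
    n = 50_000
    H = pool.haplotypes
    idx = rng.integers(0, H.shape[0], size=(n, 2))
    G = H[idx[:, 0]] + H[idx[:, 1]]
    liab = _coded_causal(G, eff) @ np.asarray(eff.effect_sizes)
    liab = liab + rng.standard_normal(n)
    return float(np.quantile(liab, 1.0 - eff.prevalence))


def _truth_record(
    pool: HaplotypePool, eff: EffectSpec, fs: FamilySet, seed: int
) -> TruthRecord:
    """Label every factor of the matching analysis model from a reference
    diplotype sample drawn from the haplotype pool."""
    rng = np.random.default_rng(seed)
    H = pool.haplotypes
    n_ref = 4000
    idx = rng.integers(0, H.shape[0], size=(n_ref, 2))
    G = H[idx[:, 0]] + H[idx[:, 1]]

    factors = panel_factors(fs, eff.inheritance)
    names = [factor_name(f, fs) for f in factors]
    cols = np.empty((n_ref, len(factors)))
    for k, f in enumerate(factors):
        j = fs.variant_index(f.variant_id)
        cols[:, k] = coded_values(f)[G[:, j]]

    causal_factors = [
        FactorCoding(f"v{j + 1}", eff.inheritance, "allele2")
        for j in eff.causal_indices
    ]
    causal_names = [factor_name(f, fs) for f in causal_factors]
    causal_cols = np.column_stack(
        [cols[:, names.index(nm)] for nm in causal_names]
    )

    labels: dict[str, str] = {}
    r2s: dict[str, float] = {}
    for k, nm in enumerate(names):
        col = cols[:, k]
        if col.std() == 0.0:
            r2 = 0.0
        else:
            r2 = max(
                (np.corrcoef(col, causal_cols[:, c])[0, 1] ** 2)
                if causal_cols[:, c].std() > 0
                else 0.0
                for c in range(causal_cols.shape[1])
            )
        r2s[nm] = float(r2)
        if nm in causal_names:
            labels[nm] = "Signal"
        elif r2 >= PROXY_R2:
            labels[nm] = "Proxy"
        else:
            labels[nm] = "Null"
    return TruthRecord(
        factor_names=names,
        labels=labels,
        r2_with_causal=r2s,
        causal_factor_names=causal_names,
        causal_variant_indices=eff.causal_indices,
    )


def simulate_families(
    pool: HaplotypePool,
    design: str,
    n_fam: int,
    eff: EffectSpec,
    seed: int = 0,
) -> tuple[FamilySet, TruthRecord]:
    """Sample nuclear families from the haplotype pool under one design.

    Parents are two random haplotypes each; every offspring receives one
    random haplotype from each parent (Mendelian transmission, no
    recombination within the locus).  ``design='trio'`` emits one offspring
    with both parental genotypes; ``design='sibpair'`` emits two full
    siblings and masks both parents.  Under affected-offspring ascertainment
    families are retained until ``n_fam`` have an affected (first) offspring;
    the run aborts if the required ascertainment rate falls below 1e-4.
    """
    if design not in ("trio", "sibpair"):
        raise ValueError("design must be 'trio' or 'sibpair'")
    if max(eff.causal_indices) >= pool.locus.p:
        raise ValueError("causal index outside the variant panel")
    rng = np.random.default_rng(seed)
    H = pool.haplotypes
    n_hap = H.shape[0]
    n_off = 1 if design == "trio" else 2
    beta = np.asarray(eff.effect_sizes)

    threshold = None
    if eff.trait == "binary":
        threshold = _liability_threshold(pool, eff, seed=pool.locus.seed + 1)

    kept_father = []
    kept_mother = []
    kept_offspring = []
    kept_pheno = []
    total_attempts = 0
    while len(kept_pheno) < n_fam:
        batch = max(256, n_fam)
        total_attempts += batch
        par = rng.integers(0, n_hap, size=(batch, 4))
        father = H[par[:, 0]] + H[par[:, 1]]
        mother = H[par[:, 2]] + H[par[:, 3]]
        # transmitted haplotype choice per offspring and parent
        pick = rng.integers(0, 2, size=(batch, n_off, 2))
        off = np.empty((batch, n_off, pool.locus.p), dtype=np.int8)
        for c in range(n_off):
            fh = np.where(pick[:, c, 0, None], par[:, 1, None], par[:, 0, None])
            mh = np.where(pick[:, c, 1, None], par[:, 3, None], par[:, 2, None])
            off[:, c] = H[fh[:, 0]] + H[mh[:, 0]]

        gen = np.stack(
            [_coded_causal(off[:, c], eff) @ beta for c in range(n_off)], axis=1
        )
        noise = rng.standard_normal((batch, n_off))
        liability = gen + noise
        if eff.trait == "binary":
            pheno = (liability > threshold).astype(float)
        else:
            pheno = liability

        if eff.ascertainment == "affected_offspring":
            keep = pheno[:, 0] > 0.5
        else:
            keep = np.ones(batch, dtype=bool)

        for b in np.nonzero(keep)[0]:
            if len(kept_pheno) >= n_fam:
                break
            kept_father.append(father[b])
            kept_mother.append(mother[b])
            kept_offspring.append(off[b])
            kept_pheno.append(pheno[b])

        if (
            eff.ascertainment == "affected_offspring"
            and total_attempts >= 50_000
            and len(kept_pheno) < total_attempts * 1e-4
        ):
            raise RuntimeError(
                f"ascertainment rate below 1e-4 ({len(kept_pheno)} families "
                f"from {total_attempts} attempts); check the effect "
                "specification and prevalence"
            )

    variants = _variant_panel(pool.locus.p)
    families = []
    for i in range(n_fam):
        offspring = []
        for c in range(n_off):
            value = float(kept_pheno[i][c])
            if eff.trait == "binary":
                child = Offspring(
                    f"o{c + 1}", kept_offspring[i][c].copy(), None, int(value)
                )
            else:
                child = Offspring(
                    f"o{c + 1}", kept_offspring[i][c].copy(), value, None
                )
            offspring.append(child)
        families.append(
            NuclearFamily(
                family_id=f"fam{i + 1:05d}",
                father_genotypes=(
                    kept_father[i].copy() if design == "trio" else None
                ),
                mother_genotypes=(
                    kept_mother[i].copy() if design == "trio" else None
                ),
                offspring=offspring,
                father_id=f"fam{i + 1:05d}_F",
                mother_id=f"fam{i + 1:05d}_M",
            )
        )
    fs = FamilySet(variants, families)
    truth = _truth_record(pool, eff, fs, seed=pool.locus.seed + 2)
    return fs, truth


def pick_causal_indices(
    pool: HaplotypePool, n_causal: int, eff_inheritance: str, rng: np.random.Generator
) -> tuple[int, ...]:
    """Random causal variant indices; recessive effects are restricted to
    variants with allele2 frequency >= 0.2 so homozygotes are non-trivial."""
    if eff_inheritance == "recessive":
        eligible = np.nonzero(pool.frequencies >= 0.2)[0]
        if eligible.size < n_causal:
            raise ValueError("too few common variants for a recessive effect")
    else:
        eligible = np.arange(pool.locus.p)
    return tuple(
        int(i) for i in sorted(rng.choice(eligible, size=n_causal, replace=False))
    )


def simulate_summary_panel(
    p: int,
    n_causal: int,
    seed: int,
    effect_scale: float = 2.5,
    ld_rho: float = 0.6,
    maf_range: tuple[float, float] = (0.1, 0.5),
    n_ref: int = 800,
    n_haplotypes: int = 2000,
) -> tuple["ZPanel", tuple[int, ...]]:
    """A z-score panel simulated directly at the summary level.

    R comes from a reference diplotype sample of a haplotype pool (additive
    coding) and ``z = Rβ + L ε`` with ``LL' = R``, matching the locus model
    the fine-mapper assumes.  Used for algorithmic checks where family-level
    data is not the object of study.
    """
    from .fbat_score import ZPanel, regularize_correlation

    rng = np.random.default_rng(seed)
    pool = simulate_haplotype_pool(
        LocusModel(
            p=p,
            maf_range=maf_range,
            ld_rho=ld_rho,
            n_haplotypes=n_haplotypes,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    H = pool.haplotypes
    idx = rng.integers(0, H.shape[0], size=(n_ref, 2))
    G = (H[idx[:, 0]] + H[idx[:, 1]]).astype(float)
    R = regularize_correlation(np.corrcoef(G, rowvar=False))

    causal = tuple(
        int(i) for i in sorted(rng.choice(p, size=n_causal, replace=False))
    )
    beta = np.zeros(p)
    for j in causal:
        beta[j] = effect_scale * rng.choice((-1.0, 1.0))
    L = np.linalg.cholesky(R + 1e-10 * np.eye(p))
    z = R @ beta + L @ rng.standard_normal(p)

    factors = [FactorCoding(f"v{j + 1}", "additive") for j in range(p)]
    names = [f"v{j + 1}:add:B" for j in range(p)]
    panel = ZPanel(
        factors=factors,
        names=names,
        z=z,
        R=R,
        n_informative=np.zeros(p, dtype=int),
        U=np.full(p, np.nan),
        V=np.full(p, np.nan),
        p_values=2.0 * norm.sf(np.abs(z)),
    )
    panel.validate()
    return panel, causal
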