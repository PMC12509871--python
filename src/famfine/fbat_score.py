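"""Family-based association score statistics and the z-score panel.

For a factor with coded offspring genotypes :math:`X_{ij}` (family *i*,
offspring *j*) and centred trait values :math:`T_{ij} = Y_{ij} - \\mu`, the
conditional score statistic is

.. math::

    U = \\sum_i \\sum_j T_{ij}\\,(X_{ij} - E[X_{ij} \\mid S_i]),
    \\qquad
    V = \\sum_i T_i' \\,\\mathrm{Cov}(X_i \\mid S_i)\\, T_i,

where the moments are taken under the conditional offspring-genotype law
given the family's sufficient statistic :math:`S_i` (see
:mod:`famfine.conditional_genotypes`).  Under the null of no linkage and no
association, :math:`z = U/\\sqrt{V}` is asymptotically standard normal
regardless of population structure.

The null correlation matrix ``R`` between factor z-scores is approximated by
the sample correlation of coded genotypes across all genotyped offspring,
using each factor's own coding, and regularized to positive semidefiniteness
(eigenvalue floor, then renormalization to unit diagonal).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .conditional_genotypes import (
    _CHILD_DIST,
    FactorCoding,
    MendelianError,
    coded_values,
)
from .family_io import MISSING, FamilySet, NuclearFamily

logger = logging.getLogger(__name__)

EIGENVALUE_FLOOR = 1e-6
DEFAULT_MIN_INFORMATIVE = 10


class ZPanelError(ValueError):
    """Too few testable factors to build a z-score panel."""


@dataclass(frozen=True)
class TraitSpec:
    """Trait type plus the offset µ subtracted from phenotypes to form T.

    ``offset=None`` resolves to the conventional default: 0 for a binary
    trait (affected-only, TDT-like contributions) and the sample mean of the
    offspring phenotypes for a quantitative trait.
    """

    trait: str = "quantitative"
    offset: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trait not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait type {self.trait!r}")
        if self.offset is not None and not np.isfinite(self.offset):
            raise ValueError("trait offset must be finite")


def resolve_offset(fs: FamilySet, trait: TraitSpec) -> float:
    if trait.offset is not None:
        return float(trait.offset)
    if trait.trait == "binary":
        return 0.0
    values = [
        off.phenotype
        for fam in fs.families
        for off in fam.offspring
        if off.phenotype is not None
    ]
    if not values:
        raise ZPanelError("no non-missing quantitative phenotypes")
    return float(np.mean(values))


def _trait_value(off, trait: TraitSpec) -> Optional[float]:
    if trait.trait == "binary":
        return None if off.affection is None else float(off.affection)
    return off.phenotype


@dataclass
class FactorResult:
    """Score, variance, z and informative-family count for one factor."""

    factor: FactorCoding
    name: str
    U: float
    V: float
    z: float
    p_value: float
    n_informative: int

    @property
    def testable(self) -> bool:
        return self.V > 0.0


@dataclass
class ZPanel:
    """Factor list with z-score vector and null correlation matrix R."""

    factors: list[FactorCoding]
    names: list[str]
    z: np.ndarray
    R: np.ndarray
    n_informative: np.ndarray
    U: np.ndarray
    V: np.ndarray
    p_values: np.ndarray
    trait: TraitSpec = field(default_factory=TraitSpec)
    offset: float = 0.0

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def validate(self) -> None:
        p = self.n_factors
        if self.z.shape != (p,) or self.R.shape != (p, p):
            raise ZPanelError("z/R dimensions do not match the factor list")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ZPanelError("R is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ZPanelError("R does not have a unit diagonal")
        if np.any(np.abs(self.R) > 1.0 + 1e-8):
            raise ZPanelError("R has entries outside [-1, 1]")


def factor_name(factor: FactorCoding, fs: FamilySet | None = None) -> str:
    """Stable factor identifier: variant, model abbreviation, coded allele."""
    allele = factor.coded_allele
    if fs is not None:
        v = fs.variants[fs.variant_index(factor.variant_id)]
        allele = v.allele1 if factor.coded_allele == "allele1" else v.allele2
    return f"{factor.variant_id}:{factor.model[:3]}:{allele}"


def _family_score_terms(
    fam: NuclearFamily,
    j: int,
    cv: np.ndarray,
    trait: TraitSpec,
    offset: float,
    variant_id: str,
) -> tuple[float, float]:
    """(u, v) contribution of one family to (U, V) for one factor.

    Inlined fast paths for the two conditioning cases; offspring with a
    missing genotype or missing phenotype contribute T=0 but genotyped
    offspring still define the conditional law.
    """
    geno = []
    tval = []
    for off in fam.offspring:
        d = off.genotypes[j]
        if d == MISSING:
            continue
        geno.append(int(d))
        y = _trait_value(off, trait)
        tval.append(0.0 if y is None else y - offset)
    n = len(geno)
    if n == 0:
        return 0.0, 0.0

    father, mother = fam.father_genotypes, fam.mother_genotypes
    if (
        father is not None
        and mother is not None
        and father[j] != MISSING
        and mother[j] != MISSING
    ):
        dist = _CHILD_DIST[int(father[j]), int(mother[j])]
        for d in geno:
            if dist[d] <= 0.0:
                raise MendelianError(fam.family_id, variant_id)
        mu = dist[0] * cv[0] + dist[1] * cv[1] + dist[2] * cv[2]
        var = (
            dist[0] * cv[0] ** 2 + dist[1] * cv[1] ** 2 + dist[2] * cv[2] ** 2
        ) - mu * mu
        if var <= 0.0:
            return 0.0, 0.0
        u = sum(t * (cv[d] - mu) for t, d in zip(tval, geno))
        v = var * sum(t * t for t in tval)
        return u, v

    if n < 2:
        return 0.0, 0.0
    c = [cv[d] for d in geno]
    mu = sum(c) / n
    s2 = sum((x - mu) ** 2 for x in c) / n
    if s2 <= 0.0:
        return 0.0, 0.0
    u = sum(t * (x - mu) for t, x in zip(tval, c))
    ts = sum(tval)
    tss = sum(t * t for t in tval)
    # T' [s²(I - J/ (n-1) off-diag)] T with Var=s², Cov=-s²/(n-1)
    v = s2 * (tss - (ts * ts - tss) / (n - 1))
    return u, max(v, 0.0)


def fbat_single(
    fs: FamilySet,
    factor: FactorCoding,
    trait: TraitSpec | None = None,
    variant_index: int | None = None,
) -> FactorResult:
    """Conditional score test for a single factor.

    Families whose conditional coded-genotype covariance is zero, or whose
    trait values are all zero after centring, contribute nothing and are not
    counted as informative.  A factor with V=0 overall is untestable
    (``z`` is NaN) and is dropped by :func:`build_zpanel`.
    """
    trait = trait or TraitSpec()
    offset = resolve_offset(fs, trait)
    j = variant_index if variant_index is not None else fs.variant_index(
        factor.variant_id
    )
    cv = coded_values(factor)
    U = V = 0.0
    n_informative = 0
    for fam in fs.families:
        try:
            u, v = _family_score_terms(
                fam, j, cv, trait, offset, factor.variant_id
            )
        except MendelianError:
            logger.warning(
                "family %s excluded at %s: Mendelian inconsistency",
                fam.family_id,
                factor.variant_id,
            )
            continue
        if v > 0.0:
            n_informative += 1
            U += u
            V += v
    if V > 0.0:
        z = U / np.sqrt(V)
        p = 2.0 * norm.sf(abs(z))
    else:
        z = np.nan
        p = np.nan
    return FactorResult(
        factor=factor,
        name=factor_name(factor, fs),
        U=U,
        V=V,
        z=float(z),
        p_value=float(p),
        n_informative=n_informative,
    )


def panel_factors(fs: FamilySet, model: str) -> list[FactorCoding]:
    """Canonical factor list for a model: one per variant under additive,
    two (one per allele) under recessive/dominant."""
    factors = []
    for v in fs.variants:
        if model == "additive":
            factors.append(FactorCoding(v.variant_id, model, "allele2"))
        else:
            factors.append(FactorCoding(v.variant_id, model, "allele1"))
            factors.append(FactorCoding(v.variant_id, model, "allele2"))
    return factors


def offspring_coded_matrix(
    fs: FamilySet, factors: Sequence[FactorCoding]
) -> np.ndarray:
    """Coded genotypes of all genotyped offspring (rows) per factor (columns),
    NaN where missing.  This is the in-sample material for estimating R."""
    dosages = np.array(
        [off.genotypes for fam in fs.families for off in fam.offspring],
        dtype=float,
    )
    dosages[dosages == MISSING] = np.nan
    out = np.full((dosages.shape[0], len(factors)), np.nan)
    for k, factor in enumerate(factors):
        j = fs.variant_index(factor.variant_id)
        cv = coded_values(factor)
        col = dosages[:, j]
        ok = ~np.isnan(col)
        out[ok, k] = cv[col[ok].astype(int)]
    return out


def regularize_correlation(R: np.ndarray, floor: float = EIGENVALUE_FLOOR) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and renormalize to a unit diagonal."""
    R = (R + R.T) / 2.0
    w, Q = np.linalg.eigh(R)
    if w.min() >= floor:
        return R
    w = np.clip(w, floor, None)
    R = (Q * w) @ Q.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def build_zpanel(
    fs: FamilySet,
    model: str = "additive",
    trait: TraitSpec | None = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> ZPanel:
    """Compute the z-score vector and offspring-estimated R for a locus.

    Factors that are monomorphic in the coded offspring data, have zero score
    variance, or fall below ``min_informative`` informative families are
    dropped (logged).  Raises :class:`ZPanelError` if fewer than two factors
    survive.
    """
    trait = trait or TraitSpec()
    offset = resolve_offset(fs, trait)
    trait = TraitSpec(trait.trait, offset)
    factors = panel_factors(fs, model)
    coded = offspring_coded_matrix(fs, factors)

    kept: list[FactorCoding] = []
    kept_cols: list[int] = []
    results: list[FactorResult] = []
    for k, factor in enumerate(factors):
        col = coded[:, k]
        finite = col[~np.isnan(col)]
        if finite.size == 0 or np.nanstd(col) == 0.0:
            logger.info("factor %s dropped: monomorphic coding", factor_name(factor, fs))
            continue
        res = fbat_single(fs, factor, trait, fs.variant_index(factor.variant_id))
        if not res.testable:
            logger.info("factor %s dropped: zero score variance", res.name)
            continue
        if res.n_informative < min_informative:
            logger.info(
                "factor %s dropped: %d informative families < %d",
                res.name,
                res.n_informative,
                min_informative,
            )
            continue
        kept.append(factor)
        kept_cols.append(k)
        results.append(res)

    if len(kept) < 2:
        raise ZPanelError(
            f"only {len(kept)} testable factor(s); at least 2 required"
        )

    sub = pd.DataFrame(coded[:, kept_cols])
    R = sub.corr(min_periods=2).to_numpy()
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    R = regularize_correlation(R)

    panel = ZPanel(
        factors=kept,
        names=[r.name for r in results],
        z=np.array([r.z for r in results]),
        R=R,
        n_informative=np.array([r.n_informative for r in results]),
        U=np.array([r.U for r in results]),
        V=np.array([r.V for r in results]),
        p_values=np.array([r.p_value for r in results]),
        trait=trait,
        offset=offset,
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# TSV dialect: a z table plus a square R matrix, loadable by the fine-mapper
# (also the entry point for externally produced z/R input).

def _write_header(fh, metadata: dict | None) -> None:
    for key, val in (metadata or {}).items():
        fh.write(f"# {key}: {val}\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def zpanel_frame(panel: ZPanel, fs: FamilySet | None = None) -> pd.DataFrame:
    rows = []
    for i, factor in enumerate(panel.factors):
        allele = factor.coded_allele
        if fs is not None:
            v = fs.variants[fs.variant_index(factor.variant_id)]
            allele = v.allele1 if factor.coded_allele == "allele1" else v.allele2
        rows.append(
            {
                "factor_id": panel.names[i],
                "variant_id": factor.variant_id,
                "model": factor.model,
                "coded_allele": allele,
                "U": panel.U[i],
                "V": panel.V[i],
                "z": panel.z[i],
                "p": panel.p_values[i],
                "n_informative": panel.n_informative[i],
            }
        )
    return pd.DataFrame(rows)


def write_zpanel(
    panel: ZPanel,
    z_path: str | Path,
    r_path: str | Path,
    fs: FamilySet | None = None,
    metadata: dict | None = None,
) -> None:
    with open(z_path, "w") as fh:
        _write_header(fh, metadata)
        zpanel_frame(panel, fs).to_csv(fh, sep="\t", index=False)
    with open(r_path, "w") as fh:
        _write_header(fh, metadata)
        pd.DataFrame(panel.R, columns=panel.names).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def load_zpanel(z_path: str | Path, r_path: str | Path) -> ZPanel:
    """Load a z table and R matrix written by :func:`write_zpanel` (or any
    externally produced files in the same dialect)."""
    zt = pd.read_csv(z_path, sep="\t", comment="#")
    R = pd.read_csv(r_path, sep="\t", comment="#")
    names = list(zt["factor_id"].astype(str))
    if list(R.columns) != names:
        raise ZPanelError("R matrix header does not match the z table factors")
    factors = []
    for _, row in zt.iterrows():
        model = str(row["model"])
        # external tables carry the allele base, not the allele1/allele2 slot;
        # the slot is only needed for re-coding genotypes, which a loaded
        # panel never does, so default to allele2 unless stated
        coded = str(row.get("coded_allele", "allele2"))
        if model == "additive" or coded not in ("allele1", "allele2"):
            coded = "allele2"
        factors.append(FactorCoding(str(row["variant_id"]), model, coded))
    panel = ZPanel(
        factors=factors,
        names=names,
        z=zt["z"].to_numpy(float),
        R=regularize_correlation(R.to_numpy(float)),
        n_informative=zt.get(
            "n_informative", pd.Series(np.zeros(len(zt)))
        ).to_numpy(int),
        U=zt.get("U", pd.Series(np.full(len(zt), np.nan))).to_numpy(float),
        V=zt.get("V", pd.Series(np.full(len(zt), np.nan))).to_numpy(float),
        p_values=zt.get("p", pd.Series(np.full(len(zt), np.nan))).to_numpy(float),
    )
    panel.validate()
    return panel
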