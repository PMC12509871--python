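"""Reading, validating and writing nuclear-family genotype/phenotype data.

The on-disk dialect is PLINK-style linkage text: a ``.ped`` file with six
leading columns (FID IID PAT MAT SEX PHENO) followed by two allele columns
per variant, and a four-column ``.map`` file (chromosome, variant id, genetic
distance, physical position).  Because ``.map`` carries no allele labels, the
allele coding (which allele is counted as the dosage allele) is fixed by
order of first appearance in the ``.ped`` and persisted in an allele-table
TSV written next to the ``.map``, so factor definitions are reproducible
across round-trips.

Genotypes are stored as dosages of ``allele2`` (0/1/2), with ``-1`` for
missing.  Phenotypes follow the PLINK convention: ``-9`` or ``0`` missing,
``1``/``2`` unaffected/affected (mapped to a 0/1 affection status), any other
numeric value a quantitative trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1

#: dosages a child can have given the two parental dosages
_POSSIBLE_CHILD = {
    (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
    (1, 0): {0, 1}, (1, 1): {0, 1, 2}, (1, 2): {1, 2},
    (2, 0): {1}, (2, 1): {1, 2}, (2, 2): {2},
}


class FamilyFormatError(ValueError):
    """Malformed or unsupported pedigree input."""


@dataclass(frozen=True)
class VariantInfo:
    """One biallelic variant: identifier, location and allele labels."""

    variant_id: str
    chromosome: str
    position: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise FamilyFormatError(
                f"variant {self.variant_id}: position must be positive"
            )
        if self.allele1 == self.allele2:
            raise FamilyFormatError(
                f"variant {self.variant_id}: alleles must differ"
            )


@dataclass
class Offspring:
    individual_id: str
    genotypes: np.ndarray  # int8 dosages of allele2, -1 missing
    phenotype: Optional[float] = None  # quantitative trait value
    affection: Optional[int] = None  # 0 unaffected / 1 affected
    sex: int = 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Offspring):
            return NotImplemented
        return (
            self.individual_id == other.individual_id
            and np.array_equal(self.genotypes, other.genotypes)
            and self.phenotype == other.phenotype
            and self.affection == other.affection
        )


@dataclass
class NuclearFamily:
    """One pedigree unit: two (possibly ungenotyped) parents, >=1 offspring."""

    family_id: str
    father_genotypes: Optional[np.ndarray]
    mother_genotypes: Optional[np.ndarray]
    offspring: list[Offspring]
    father_id: str = "F"
    mother_id: str = "M"

    def __post_init__(self) -> None:
        if not self.offspring:
            raise FamilyFormatError(
                f"family {self.family_id}: at least one offspring required"
            )

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NuclearFamily):
            return NotImplemented

        def _eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(a, b)

        return (
            self.family_id == other.family_id
            and _eq(self.father_genotypes, other.father_genotypes)
            and _eq(self.mother_genotypes, other.mother_genotypes)
            and self.offspring == other.offspring
        )


@dataclass
class FamilySet:
    """A variant panel together with the nuclear families typed on it."""

    variants: list[VariantInfo]
    families: list[NuclearFamily]
    mendel_errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.variant_id == variant_id:
                return i
        raise KeyError(variant_id)

    def validate(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise FamilyFormatError("duplicate variant ids in panel")
        seen: set[tuple[str, str]] = set()
        p = self.n_variants
        for fam in self.families:
            for vec in (fam.father_genotypes, fam.mother_genotypes):
                if vec is not None and len(vec) != p:
                    raise FamilyFormatError(
                        f"family {fam.family_id}: parental genotype length "
                        f"{len(vec)} != panel size {p}"
                    )
            for off in fam.offspring:
                key = (fam.family_id, off.individual_id)
                if key in seen:
                    raise FamilyFormatError(
                        f"duplicate individual {key[1]} in family {key[0]}"
                    )
                seen.add(key)
                if len(off.genotypes) != p:
                    raise FamilyFormatError(
                        f"{key}: genotype length {len(off.genotypes)} != {p}"
                    )
                bad = ~np.isin(off.genotypes, (MISSING, 0, 1, 2))
                if bad.any():
                    raise FamilyFormatError(f"{key}: invalid dosage values")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilySet):
            return NotImplemented
        return self.variants == other.variants and self.families == other.families


def _allele_table_path(map_path: Path) -> Path:
    return map_path.with_suffix(".alleles.tsv")


def _parse_phenotype(token: str) -> tuple[Optional[float], Optional[int]]:
    """PLINK phenotype column -> (quantitative value, affection status)."""
    if token in ("-9", "0"):
        return None, None
    if token == "1":
        return None, 0
    if token == "2":
        return None, 1
    try:
        value = float(token)
    except ValueError as exc:
        raise FamilyFormatError(f"unparseable phenotype {token!r}") from exc
    if value in (-9.0, 0.0):
        return None, None
    return value, None


def _format_phenotype(off: Offspring) -> str:
    if off.affection is not None:
        return str(off.affection + 1)
    if off.phenotype is not None:
        return repr(float(off.phenotype))
    return "-9"


def load_families(
    ped_path: str | Path,
    map_path: str | Path,
    allele_path: str | Path | None = None,
) -> FamilySet:
    """Load a FamilySet from PLINK-style ``.ped``/``.map`` text files.

    Rows sharing a family id are assembled into one nuclear family: rows with
    PAT=MAT=0 are the parents, all other rows are offspring and must point at
    the same parental pair.  Parents referenced but absent from the file yield
    missing parental genotype vectors.  Offspring genotypes that are
    Mendelian-impossible given two genotyped parents are recorded in
    ``FamilySet.mendel_errors`` and the family's offspring genotypes at that
    variant are set missing (the family is excluded there), with a warning.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    variants_raw: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise FamilyFormatError(
                    f"{map_path}: expected 4 columns, got {len(tok)}"
                )
            variants_raw.append((tok[0], tok[1], int(tok[3])))
    p = len(variants_raw)

    rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * p:
                raise FamilyFormatError(
                    f"{ped_path} line {ln}: expected {6 + 2 * p} fields for "
                    f"{p} variants, got {len(tok)}"
                )
            rows.append(tok)

    # allele coding: explicit table beats first-appearance scan
    if allele_path is None and _allele_table_path(map_path).exists():
        allele_path = _allele_table_path(map_path)
    alleles: list[list[str]] = [[] for _ in range(p)]
    if allele_path is not None:
        import csv

        with open(allele_path) as fh:
            reader = csv.reader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            )
            header = next(reader)
            if header[:3] != ["variant_id", "allele1", "allele2"]:
                raise FamilyFormatError(f"{allele_path}: bad allele table header")
            table = {r[0]: (r[1], r[2]) for r in reader}
        for j, (_, vid, _) in enumerate(variants_raw):
            if vid not in table:
                raise FamilyFormatError(f"{allele_path}: missing variant {vid}")
            alleles[j] = [a for a in table[vid] if a != "0"]
    else:
        for tok in rows:
            for j in range(p):
                for a in (tok[6 + 2 * j], tok[7 + 2 * j]):
                    if a != "0" and a not in alleles[j]:
                        alleles[j].append(a)

    variants = []
    for j, (chrom, vid, pos) in enumerate(variants_raw):
        seen = alleles[j]
        if len(seen) > 2:
            raise FamilyFormatError(
                f"variant {vid}: more than two alleles ({seen}); "
                "multi-allelic variants are not supported"
            )
        a1 = seen[0] if len(seen) >= 1 else "1"
        a2 = seen[1] if len(seen) == 2 else "0" if a1 != "0" else "?"
        variants.append(VariantInfo(vid, chrom, pos, a1, a2))

    def _dosages(tok: list[str]) -> np.ndarray:
        g = np.empty(p, dtype=np.int8)
        for j in range(p):
            a, b = tok[6 + 2 * j], tok[7 + 2 * j]
            if a == "0" or b == "0":
                g[j] = MISSING
                continue
            v = variants[j]
            d = 0
            for al in (a, b):
                if al == v.allele2:
                    d += 1
                elif al != v.allele1:
                    raise FamilyFormatError(
                        f"variant {v.variant_id}: unexpected allele {al!r}"
                    )
            g[j] = d
        return g

    by_fid: dict[str, list[list[str]]] = {}
    for tok in rows:
        by_fid.setdefault(tok[0], []).append(tok)

    families: list[NuclearFamily] = []
    mendel_errors: list[tuple[str, str]] = []
    for fid, ftoks in by_fid.items():
        founders = {t[1]: t for t in ftoks if t[2] == "0" and t[3] == "0"}
        children = [t for t in ftoks if not (t[2] == "0" and t[3] == "0")]
        if not children:
            raise FamilyFormatError(f"family {fid}: no offspring rows")
        pairs = {(t[2], t[3]) for t in children}
        if len(pairs) > 1:
            raise FamilyFormatError(
                f"family {fid}: offspring point at different parental pairs "
                "(half-siblings or multiple sibships are not supported)"
            )
        if any(t[2] == "0" or t[3] == "0" for t in children):
            raise FamilyFormatError(
                f"family {fid}: offspring with a single named parent are not "
                "supported"
            )
        pat, mat = next(iter(pairs))
        child_ids = {t[1] for t in children}
        if child_ids & {pat, mat}:
            raise FamilyFormatError(
                f"family {fid}: multi-generation pedigrees are not supported"
            )
        extra = set(founders) - {pat, mat}
        if extra:
            raise FamilyFormatError(
                f"family {fid}: founder rows {sorted(extra)} are not parents "
                "of the sibship"
            )
        father = _dosages(founders[pat]) if pat in founders else None
        mother = _dosages(founders[mat]) if mat in founders else None
        offspring = []
        for t in children:
            pheno, aff = _parse_phenotype(t[5])
            offspring.append(
                Offspring(t[1], _dosages(t), pheno, aff, sex=int(float(t[4])))
            )
        fam = NuclearFamily(fid, father, mother, offspring, pat, mat)
        if father is not None and mother is not None:
            for j, v in enumerate(variants):
                gf, gm = int(father[j]), int(mother[j])
                if gf == MISSING or gm == MISSING:
                    continue
                bad = any(
                    off.genotypes[j] != MISSING
                    and int(off.genotypes[j]) not in _POSSIBLE_CHILD[(gf, gm)]
                    for off in fam.offspring
                )
                if bad:
                    mendel_errors.append((fid, v.variant_id))
                    logger.warning(
                        "family %s, variant %s: Mendelian inconsistency; "
                        "family excluded for this variant",
                        fid,
                        v.variant_id,
                    )
                    for off in fam.offspring:
                        off.genotypes[j] = MISSING
        families.append(fam)

    fs = FamilySet(variants, families, mendel_errors)
    fs.validate()
    return fs


def write_families(
    fs: FamilySet,
    ped_path: str | Path,
    map_path: str | Path,
    allele_path: str | Path | None = None,
) -> None:
    """Write a FamilySet as ``.ped``/``.map`` plus the allele-coding table.

    ``load_families(write_families(fs))`` reproduces ``fs`` exactly
    (genotypes, missingness, phenotypes).  Missing parents are represented by
    PAT/MAT ids with no corresponding rows.
    """
    fs.validate()
    ped_path, map_path = Path(ped_path), Path(map_path)
    if allele_path is None:
        allele_path = _allele_table_path(map_path)

    with open(map_path, "w") as fh:
        for v in fs.variants:
            fh.write(f"{v.chromosome}\t{v.variant_id}\t0\t{v.position}\n")
    with open(allele_path, "w") as fh:
        fh.write("variant_id\tallele1\tallele2\n")
        for v in fs.variants:
            fh.write(f"{v.variant_id}\t{v.allele1}\t{v.allele2}\n")

    def _geno_fields(g: np.ndarray) -> list[str]:
        out = []
        for j, v in enumerate(fs.variants):
            d = int(g[j])
            if d == MISSING:
                out += ["0", "0"]
            else:
                out += [v.allele2 if k <= d else v.allele1 for k in (1, 2)]
        return out

    with open(ped_path, "w") as fh:
        for fam in fs.families:
            if fam.father_genotypes is not None:
                fh.write(
                    " ".join(
                        [fam.family_id, fam.father_id, "0", "0", "1", "-9"]
                        + _geno_fields(fam.father_genotypes)
                    )
                    + "\n"
                )
            if fam.mother_genotypes is not None:
                fh.write(
                    " ".join(
                        [fam.family_id, fam.mother_id, "0", "0", "2", "-9"]
                        + _geno_fields(fam.mother_genotypes)
                    )
                    + "\n"
                )
            for off in fam.offspring:
                fh.write(
                    " ".join(
                        [
                            fam.family_id,
                            off.individual_id,
                            fam.father_id,
                            fam.mother_id,
                            str(off.sex),
                            _format_phenotype(off),
                        ]
                        + _geno_fields(off.genotypes)
                    )
                    + "\n"
                )
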