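import numpy as np
import pytest

from famfine.family_io import FamilySet, NuclearFamily, Offspring, VariantInfo


def make_variants(p):
    return [
        VariantInfo(f"v{j + 1}", "1", 1 + 1000 * j, "A", "B") for j in range(p)
    ]


def make_trio(fid, father, mother, child, phenotype=1.0, affection=None, p=None):
    """One trio with dosage vectors (ints or lists)."""
    father = np.atleast_1d(np.asarray(father, dtype=np.int8))
    mother = np.atleast_1d(np.asarray(mother, dtype=np.int8))
    child = np.atleast_1d(np.asarray(child, dtype=np.int8))
    return NuclearFamily(
        fid,
        father,
        mother,
        [Offspring("o1", child, phenotype, affection)],
        f"{fid}_F",
        f"{fid}_M",
    )


def make_sibship(fid, genotypes, phenotypes):
    """Siblings with missing parental genotypes."""
    offspring = [
        Offspring(f"o{i + 1}", np.atleast_1d(np.asarray(g, dtype=np.int8)), y, None)
        for i, (g, y) in enumerate(zip(genotypes, phenotypes))
    ]
    return NuclearFamily(fid, None, None, offspring, f"{fid}_F", f"{fid}_M")


@pytest.fixture
def single_variant_panel():
    return make_variants(1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_familyset(rng, p=3, n_fam=5):
    """Randomized valid FamilySet mixing trios and sibships, with missingness."""
    variants = make_variants(p)
    families = []
    for i in range(n_fam):
        fid = f"f{i + 1}"
        if rng.random() < 0.5:
            gf = rng.integers(0, 3, p).astype(np.int8)
            gm = rng.integers(0, 3, p).astype(np.int8)
            child = np.empty(p, dtype=np.int8)
            for j in range(p):
                tf = 1 if gf[j] == 2 else (0 if gf[j] == 0 else rng.integers(0, 2))
                tm = 1 if gm[j] == 2 else (0 if gm[j] == 0 else rng.integers(0, 2))
                child[j] = tf + tm
            pheno = (None, 1.0, 2.0, 3.5)[rng.integers(0, 4)]
            aff = int(rng.integers(0, 2)) if pheno is None and rng.random() < 0.5 else None
            fam = NuclearFamily(
                fid, gf, gm,
                [Offspring("o1", child, pheno, aff)],
                f"{fid}_F", f"{fid}_M",
            )
        else:
            n_off = int(rng.integers(1, 4))
            offspring = []
            for c in range(n_off):
                g = rng.integers(0, 3, p).astype(np.int8)
                g[rng.random(p) < 0.1] = -1
                offspring.append(Offspring(f"o{c + 1}", g, float(rng.normal()), None))
            fam = NuclearFamily(fid, None, None, offspring, f"{fid}_F", f"{fid}_M")
        families.append(fam)
    fs = FamilySet(variants, families)
    fs.validate()
    return fs
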