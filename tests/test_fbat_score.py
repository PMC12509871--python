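"""Conditional score tests, z-panel construction and R estimation."""

import numpy as np
import pytest

from famfine.conditional_genotypes import (
    FactorCoding,
    moments_from_conditional,
    offspring_conditional,
)
from famfine.family_io import FamilySet
from famfine.fbat_score import (
    TraitSpec,
    ZPanelError,
    build_zpanel,
    fbat_single,
    load_zpanel,
    offspring_coded_matrix,
    panel_factors,
    regularize_correlation,
    write_zpanel,
)
from famfine.simulate import (
    EffectSpec,
    LocusModel,
    simulate_families,
    simulate_haplotype_pool,
)

from conftest import make_sibship, make_trio, make_variants

ADD = FactorCoding("v1", "additive")


def oracle_fbat(fs, factor, trait):
    """Independent recomputation: enumerate each family's conditional support
    directly and accumulate exact moments (no closed-form shortcuts)."""
    from famfine.fbat_score import resolve_offset, _trait_value

    offset = resolve_offset(fs, trait)
    j = fs.variant_index(factor.variant_id)
    U = V = 0.0
    for fam in fs.families:
        cond = offspring_conditional(fam, j)
        mom = moments_from_conditional(cond, factor)
        T = []
        obs = []
        from famfine.conditional_genotypes import coded_values

        cv = coded_values(factor)
        for i in cond.offspring_index:
            off = fam.offspring[i]
            y = _trait_value(off, trait)
            T.append(0.0 if y is None else y - offset)
            obs.append(cv[int(off.genotypes[j])])
        T = np.asarray(T)
        obs = np.asarray(obs)
        v = float(T @ mom.covariance_matrix @ T)
        if v > 0:
            U += float(T @ (obs - mom.mean_vector))
            V += v
    return U, V, U / np.sqrt(V) if V > 0 else np.nan


class TestFbatSingle:
    def test_single_trio_example(self):
        fs = FamilySet(
            make_variants(1),
            [make_trio("f1", 1, 1, 2, phenotype=None, affection=1)],
        )
        res = fbat_single(fs, ADD, TraitSpec("binary", 0.0))
        assert res.U == pytest.approx(1.0)
        assert res.V == pytest.approx(0.5)
        assert res.z == pytest.approx(np.sqrt(2.0))
        assert res.n_informative == 1

    def test_sib_pair_example(self):
        fs = FamilySet(
            make_variants(1), [make_sibship("f1", [[2], [1]], [1.0, 0.0])]
        )
        res = fbat_single(fs, ADD, TraitSpec("quantitative", 0.0))
        assert res.U == pytest.approx(0.5)
        assert res.V == pytest.approx(0.25)
        assert res.z == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_null_trios(self):
        """200 simulated null trios: the table-driven score equals a
        brute-force recomputation that enumerates every family's conditional
        distribution."""
        pool = simulate_haplotype_pool(
            LocusModel(p=3, maf_range=(0.2, 0.45), ld_rho=0.3, seed=42)
        )
        eff = EffectSpec(causal_indices=(0,), effect_sizes=[0.0])
        fs, _ = simulate_families(pool, "trio", 200, eff, seed=7)
        trait = TraitSpec("quantitative")
        for vid in ("v1", "v2", "v3"):
            for model, allele in (
                ("additive", "allele2"),
                ("recessive", "allele2"),
                ("dominant", "allele1"),
            ):
                factor = FactorCoding(vid, model, allele)
                res = fbat_single(fs, factor, trait)
                U, V, z = oracle_fbat(fs, factor, trait)
                assert res.U == pytest.approx(U, abs=1e-9)
                assert res.V == pytest.approx(V, abs=1e-9)
                if res.testable:
                    assert res.z == pytest.approx(z, abs=1e-9)

    def test_matches_enumeration_oracle_on_sibships(self, rng):
        from conftest import random_familyset

        fs = random_familyset(rng, p=2, n_fam=40)
        trait = TraitSpec("quantitative")
        for vid in ("v1", "v2"):
            factor = FactorCoding(vid, "additive")
            res = fbat_single(fs, factor, trait)
            U, V, _ = oracle_fbat(fs, factor, trait)
            assert res.U == pytest.approx(U, abs=1e-9)
            assert res.V == pytest.approx(V, abs=1e-9)

    def test_duplicating_families_scales_z_by_sqrt2(self):
        pool = simulate_haplotype_pool(LocusModel(p=2, ld_rho=0.2, seed=3))
        eff = EffectSpec(causal_indices=(0,), effect_sizes=[0.3])
        fs, _ = simulate_families(pool, "trio", 100, eff, seed=5)
        doubled = FamilySet(
            fs.variants,
            fs.families
            + [
                type(f)(
                    f.family_id + "dup",
                    f.father_genotypes,
                    f.mother_genotypes,
                    [
                        type(o)(o.individual_id, o.genotypes, o.phenotype, o.affection)
                        for o in f.offspring
                    ],
                    f.father_id,
                    f.mother_id,
                )
                for f in fs.families
            ],
        )
        trait = TraitSpec("quantitative", 0.0)
        r1 = fbat_single(fs, ADD, trait)
        r2 = fbat_single(doubled, ADD, trait)
        assert r2.U == pytest.approx(2 * r1.U)
        assert r2.V == pytest.approx(2 * r1.V)
        assert r2.z == pytest.approx(np.sqrt(2) * r1.z)

    def test_untestable_factor_flagged(self):
        fs = FamilySet(
            make_variants(1), [make_trio("f1", 0, 0, 0, phenotype=1.0)]
        )
        res = fbat_single(fs, ADD, TraitSpec("quantitative", 0.0))
        assert not res.testable
        assert np.isnan(res.z)


@pytest.fixture(scope="module")
def sim():
    pool = simulate_haplotype_pool(
        LocusModel(p=8, maf_range=(0.25, 0.45), ld_rho=0.5, seed=11)
    )
    eff = EffectSpec(causal_indices=(2,), effect_sizes=[0.4])
    fs, _ = simulate_families(pool, "trio", 400, eff, seed=13)
    return fs


class TestZPanel:

    def test_additive_panel_one_factor_per_variant(self, sim):
        panel = build_zpanel(sim, model="additive")
        assert panel.n_factors == 8
        assert np.allclose(np.diag(panel.R), 1.0)
        variants = [f.variant_id for f in panel.factors]
        assert variants == [f"v{j}" for j in range(1, 9)]

    def test_recessive_panel_two_factors_per_variant(self, sim):
        panel = build_zpanel(sim, model="recessive", min_informative=5)
        per_variant = {}
        for f in panel.factors:
            per_variant.setdefault(f.variant_id, []).append(f.coded_allele)
        # common variants: both homozygote classes present -> both alleles
        assert all(len(v) <= 2 for v in per_variant.values())
        assert any(len(v) == 2 for v in per_variant.values())

    def test_r_offdiagonal_matches_direct_correlation(self, sim):
        panel = build_zpanel(sim, model="additive")
        coded = offspring_coded_matrix(sim, panel.factors)
        direct = np.corrcoef(coded[:, 0], coded[:, 3])[0, 1]
        assert panel.R[0, 3] == pytest.approx(direct, abs=1e-8)

    def test_identical_columns_identical_z_and_rows(self, sim):
        # duplicate v3 by appending a copy of its genotypes as a new variant
        from famfine.family_io import VariantInfo

        variants = sim.variants + [VariantInfo("v3b", "1", 99_000, "A", "B")]
        families = []
        for fam in sim.families:
            fam2 = type(fam)(
                fam.family_id,
                np.append(fam.father_genotypes, fam.father_genotypes[2]),
                np.append(fam.mother_genotypes, fam.mother_genotypes[2]),
                [
                    type(o)(
                        o.individual_id,
                        np.append(o.genotypes, o.genotypes[2]),
                        o.phenotype,
                        o.affection,
                    )
                    for o in fam.offspring
                ],
                fam.father_id,
                fam.mother_id,
            )
            families.append(fam2)
        fs2 = FamilySet(variants, families)
        panel = build_zpanel(fs2, model="additive")
        i, j = panel.names.index("v3:add:B"), panel.names.index("v3b:add:B")
        assert panel.z[i] == pytest.approx(panel.z[j], abs=1e-12)
        # regularization floors eigenvalues at 1e-6, so r = 1 - O(1e-6)
        assert panel.R[i, j] == pytest.approx(1.0, abs=1e-5)

    def test_min_informative_drops_factors(self, sim):
        panel = build_zpanel(sim, model="additive", min_informative=10)
        huge = 10**6
        with pytest.raises(ZPanelError):
            build_zpanel(sim, model="additive", min_informative=huge)
        assert panel.n_factors >= 2

    def test_roundtrip_tsv(self, sim, tmp_path):
        panel = build_zpanel(sim, model="additive")
        zp, rp = tmp_path / "z.tsv", tmp_path / "R.tsv"
        write_zpanel(panel, zp, rp, sim, {"note": "test"})
        back = load_zpanel(zp, rp)
        assert back.names == panel.names
        assert back.z == pytest.approx(panel.z, abs=1e-9)
        assert np.allclose(back.R, panel.R, atol=1e-8)


def test_regularize_correlation_floors_eigenvalues():
    R = np.array([[1.0, 1.0], [1.0, 1.0]])
    out = regularize_correlation(R)
    w = np.linalg.eigvalsh(out)
    assert w.min() > 0
    assert np.allclose(np.diag(out), 1.0)


def test_panel_factors_counts():
    fs = FamilySet(make_variants(4), [make_trio("f1", [1] * 4, [1] * 4, [1] * 4)])
    assert len(panel_factors(fs, "additive")) == 4
    assert len(panel_factors(fs, "recessive")) == 8
    assert len(panel_factors(fs, "dominant")) == 8
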