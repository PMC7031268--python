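"""Synthetic-data generator: pedigree, gene drop, polygenic values, QTN
phenotypes and fertility records."""

import numpy as np
import pytest

import domvar
from domvar.pedigree import UNKNOWN
from domvar.simulate import (
    FertilityParams,
    SimulationScenario,
    gene_drop_genotypes,
    qtn_effects,
    simulate_fertility_records,
    simulate_pedigree,
    simulate_polygenic,
    simulate_qtn_phenotypes,
)


class TestSimulatePedigree:
    def test_zero_generations_gives_founders_only(self):
        ped = simulate_pedigree(10, 0, 2, 2, seed=1)
        assert ped.n == 10
        assert ped.is_founder.all()

    def test_every_nonfounder_has_two_known_parents(self):
        ped = simulate_pedigree(40, 3, 5, 3, seed=2)
        nf = ~ped.is_founder
        assert (ped.sire[nf] != UNKNOWN).all()
        assert (ped.dam[nf] != UNKNOWN).all()

    def test_half_sib_family_size(self):
        ped = simulate_pedigree(200, 1, 10, 4, seed=3)
        gen1 = np.flatnonzero(ped.generation == 1)
        sires, counts = np.unique(ped.sire[gen1], return_counts=True)
        assert len(sires) <= 10
        # 100 dams x 4 offspring over <=10 sires
        assert counts.mean() == pytest.approx(len(gen1) / len(sires))
        assert counts.mean() >= 30

    def test_no_male_candidates_errors(self):
        # a single offspring per generation is assigned female, so the
        # second generation has no sires to draw from
        with pytest.raises(ValueError, match="candidates"):
            simulate_pedigree(2, 2, 1, 1, seed=4)

    def test_deterministic_under_seed(self):
        p1 = simulate_pedigree(30, 2, 4, 3, seed=9)
        p2 = simulate_pedigree(30, 2, 4, 3, seed=9)
        assert list(p1.ids) == list(p2.ids)
        np.testing.assert_array_equal(p1.sire, p2.sire)


class TestGeneDrop:
    def test_fixed_allele_stays_fixed(self):
        ped = simulate_pedigree(10, 2, 2, 2, seed=5)
        g = gene_drop_genotypes(ped, founder_freqs=np.array([1.0, 0.0]), seed=6)
        assert (g.codes[:, 0] == 2).all()
        assert (g.codes[:, 1] == 0).all()

    @pytest.mark.parametrize("recombination", [False, True])
    def test_mendelian_consistency_exhaustive(self, recombination):
        ped = simulate_pedigree(12, 3, 3, 3, seed=7)
        g = gene_drop_genotypes(
            ped, founder_freqs=np.full(40, 0.4), seed=8, recombination=recombination
        )
        codes = g.codes
        for i in np.flatnonzero(~ped.is_founder):
            s, d = ped.sire[i], ped.dam[i]
            for par in (s, d):
                # child shares at least one allele with each parent
                impossible = ((codes[i] == 0) & (codes[par] == 2)) | (
                    (codes[i] == 2) & (codes[par] == 0)
                )
                assert not impossible.any()

    def test_realized_frequency_binomial(self):
        # wide mating design keeps drift near the founder binomial error
        ped = simulate_pedigree(400, 1, 200, 2, seed=10)
        freqs = np.full(30, 0.3)
        g = gene_drop_genotypes(ped, founder_freqs=freqs, seed=11)
        term = np.asarray(ped.generation) == 1
        realized = g.codes[term].mean(axis=0) / 2
        se = np.sqrt(0.3 * 0.7 / (2 * 400))  # founder sampling
        assert (np.abs(realized - 0.3) < 6 * se).all()
        assert abs(realized.mean() - 0.3) < 3 * se / np.sqrt(30) * 2

    def test_deterministic_under_seed(self):
        ped = simulate_pedigree(20, 2, 3, 2, seed=12)
        g1 = gene_drop_genotypes(ped, founder_freqs=np.full(15, 0.25), seed=13)
        g2 = gene_drop_genotypes(ped, founder_freqs=np.full(15, 0.25), seed=13)
        np.testing.assert_array_equal(g1.codes, g2.codes)


class TestSimulatePolygenic:
    def test_zero_variance_gives_zeros(self, small_pedigree):
        pv = simulate_polygenic(small_pedigree, 0.0, seed=1)
        assert (pv.values == 0).all()

    def test_offspring_conditional_variance_noninbred(self):
        # many repeated full-sib offspring of the same two founders:
        # conditional variance (1/4 + 1/4) sigma_u2 = 0.5
        recs = [("S", 0, 0), ("D", 0, 0)] + [(f"C{i}", "S", "D") for i in range(4000)]
        ped = domvar.Pedigree.from_parent_map(recs)
        pv = simulate_polygenic(ped, 2.0, seed=21)
        vals = dict(zip(map(str, ped.ids), pv.values))
        kids = np.array([vals[f"C{i}"] for i in range(4000)])
        mid = 0.5 * (vals["S"] + vals["D"])
        assert kids.mean() == pytest.approx(mid, abs=0.08)
        assert kids.var() == pytest.approx(0.5 * 2.0, rel=0.1)

    def test_full_sib_covariance(self):
        # 5000 independent founder pairs, two offspring each: Cov = 0.5 sigma_u2
        recs = []
        for k in range(5000):
            recs += [
                (f"S{k}", 0, 0),
                (f"D{k}", 0, 0),
                (f"A{k}", f"S{k}", f"D{k}"),
                (f"B{k}", f"S{k}", f"D{k}"),
            ]
        ped = domvar.Pedigree.from_parent_map(recs)
        pv = simulate_polygenic(ped, 1.0, seed=22)
        vals = dict(zip(map(str, ped.ids), pv.values))
        a = np.array([vals[f"A{k}"] for k in range(5000)])
        b = np.array([vals[f"B{k}"] for k in range(5000)])
        cov = np.cov(a, b)[0, 1]
        assert cov == pytest.approx(0.5, abs=0.06)

    def test_inbred_parent_shrinks_sampling_variance(self):
        # parents are offspring of full sibs (F = 0.25) so the offspring
        # Mendelian sampling variance is 2 * 1/4 (1 - 0.25) = 0.375
        recs = [("A", 0, 0), ("B", 0, 0), ("X1", "A", "B"), ("X2", "A", "B")]
        recs += [(f"P{k}", "X1", "X2") for k in range(2)]
        recs += [(f"C{k}", "P0", "P1") for k in range(6000)]
        ped = domvar.Pedigree.from_parent_map(recs)
        F = dict(zip(map(str, ped.ids), ped.inbreeding()))
        assert F["P0"] == pytest.approx(0.25)
        pv = simulate_polygenic(ped, 1.0, seed=23)
        vals = dict(zip(map(str, ped.ids), pv.values))
        kids = np.array([vals[f"C{k}"] for k in range(6000)])
        assert kids.var() == pytest.approx(0.375, rel=0.08)

    def test_unsorted_pedigree_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            domvar.Pedigree(
                np.array(["kid", "mum"], dtype=object),
                np.array([-1, -1]),
                np.array([1, -1]),
            )


class TestQtnEffects:
    @pytest.mark.parametrize(
        "p,f,h,a_expected",
        [
            (0.5, 0.10, -1.0, 0.4472135955),
            (0.19, 0.05, 1.0, 0.4030424),
        ],
    )
    def test_scaling_algebra(self, p, f, h, a_expected):
        a, d = qtn_effects(p, f, h, sigma_u2=1.0)
        assert a == pytest.approx(a_expected, rel=1e-4)
        assert d == pytest.approx(h * a)
        assert 2 * p * (1 - p) * a**2 == pytest.approx(f)

    def test_no_dominance_when_h_zero(self):
        assert qtn_effects(0.3, 0.05, 0.0)[1] == 0.0

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_fixed_allele_rejected(self, p):
        with pytest.raises(ValueError):
            qtn_effects(p, 0.05, 1.0)


class TestQtnPhenotypes:
    def test_no_qtn_no_noise_equals_polygenic(self):
        ped = simulate_pedigree(20, 2, 3, 2, seed=30)
        g = gene_drop_genotypes(ped, founder_freqs=np.full(10, 0.5), seed=31)
        scen = SimulationScenario(
            qtn_positions=(), qtn_mafs=(), var_fraction=0.1, sigma_e2=0.0
        )
        pv = simulate_polygenic(ped, 1.0, seed=32)
        y = simulate_qtn_phenotypes(g, ped, scen, seed=33, polygenic=pv)
        np.testing.assert_allclose(y, pv.values[ped.positions(g.ids)])

    def test_variance_decomposition(self):
        ped = simulate_pedigree(300, 1, 10, 4, seed=34)
        g = gene_drop_genotypes(ped, founder_freqs=np.full(3, 0.5), seed=35)
        scen = SimulationScenario(
            qtn_positions=tuple(g.snp_map["bp"]),
            qtn_mafs=(0.5, 0.5, 0.5),
            var_fraction=0.5,
            dominance_ratio=0.0,
            sigma_u2=1.0,
            sigma_e2=4.0,
        )
        ys = np.concatenate(
            [simulate_qtn_phenotypes(g, ped, scen, seed=36 + r) for r in range(60)]
        )
        expect = 1.0 + 3 * 0.5 + 4.0  # sigma_u2 + sum V_qtn + sigma_e2
        assert np.var(ys) == pytest.approx(expect, rel=0.08)

    def test_heterozygote_deviation_matches_d(self):
        ped = simulate_pedigree(2000, 0, 1, 1, seed=37)
        g = gene_drop_genotypes(ped, founder_freqs=np.array([0.5]), seed=38)
        scen = SimulationScenario(
            qtn_positions=(1,), qtn_mafs=(0.5,), var_fraction=0.2,
            dominance_ratio=1.0, sigma_e2=0.5,
        )
        a, d = qtn_effects(0.5, 0.2, 1.0)
        reps = [
            simulate_qtn_phenotypes(g, ped, scen, seed=40 + r, orient="alt")
            for r in range(40)
        ]
        het = np.concatenate([y[g.codes[:, 0] == 1] for y in reps])
        hom0 = np.concatenate([y[g.codes[:, 0] == 0] for y in reps])
        hom2 = np.concatenate([y[g.codes[:, 0] == 2] for y in reps])
        dev = het.mean() - 0.5 * (hom0.mean() + hom2.mean())
        assert dev == pytest.approx(d, abs=0.03)

    def test_monomorphic_qtn_warns(self):
        ped = simulate_pedigree(10, 0, 1, 1, seed=41)
        g = gene_drop_genotypes(ped, founder_freqs=np.array([1.0]), seed=42)
        scen = SimulationScenario(qtn_positions=(1,), qtn_mafs=(0.1,), var_fraction=0.05)
        with pytest.warns(UserWarning, match="monomorphic"):
            simulate_qtn_phenotypes(g, ped, scen, seed=43)

    def test_orientation_attaches_plus_a_to_major_class(self):
        ped = simulate_pedigree(5000, 0, 1, 1, seed=44)
        g = gene_drop_genotypes(ped, founder_freqs=np.array([0.1]), seed=45)
        scen = SimulationScenario(
            qtn_positions=(1,), qtn_mafs=(0.1,), var_fraction=0.3,
            dominance_ratio=0.0, sigma_e2=1e-12,
        )
        y = simulate_qtn_phenotypes(g, ped, scen, seed=46, orient="major")
        # allele-2 frequency 0.1 -> code 0 is the major homozygote -> +a
        assert y[g.codes[:, 0] == 0].mean() > y[g.codes[:, 0] == 2].mean()


class TestFertilityRecords:
    def test_censor_rate_zero(self):
        ped = simulate_pedigree(60, 1, 5, 2, seed=50)
        rec = simulate_fertility_records(
            ped, params=FertilityParams(censor_rate=0.0), seed=51
        )
        assert not rec["censored"].any()

    def test_default_trait_levels(self):
        ped = simulate_pedigree(400, 2, 10, 3, seed=52)
        rec = simulate_fertility_records(ped, seed=53)
        heifer = rec[rec["stage"] == "heifer"]
        cow = rec[rec["stage"] == "cow"]
        assert heifer["IFL"].mean() == pytest.approx(29.7, abs=4.0)
        assert cow["ICF"].mean() == pytest.approx(49.2, abs=6.0)
        assert set(cow["parity"].unique()) <= {1, 2, 3}

    def test_censored_fraction_binomial(self):
        ped = simulate_pedigree(400, 2, 10, 3, seed=54)
        rec = simulate_fertility_records(ped, seed=55)
        frac = rec["censored"].mean()
        se = np.sqrt(0.15 * 0.85 / len(rec))
        assert frac == pytest.approx(0.15, abs=4 * se)
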