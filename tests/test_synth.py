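import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from walnutkit.haploblocks import Pedigree
from walnutkit.io_windows import tile_windows
from walnutkit.map_anchor import assign_order_orient, filter_probe_alignments
from walnutkit.stats import fst_from_components, wc_fst_components
from walnutkit.synth import (
    TwoPopSimConfig,
    simulate_anchoring_fixture,
    simulate_pedigree_genotypes,
    simulate_two_population,
    simulate_two_population_vcf,
    uniform_genetic_map,
)


class TestTwoPopulation:
    def test_seed_reproducibility_byte_identical(self, tmp_path):
        cfg = TwoPopSimConfig(n_sites=500, seed=9)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        simulate_two_population_vcf(cfg, p1)
        simulate_two_population_vcf(cfg, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_dosages_and_frequencies_in_bounds(self):
        mat, truth = simulate_two_population(TwoPopSimConfig(n_sites=2000, seed=1))
        assert set(np.unique(mat.calls)) <= {0, 1, 2}
        for f in truth.pop_freqs.values():
            assert ((f >= 0) & (f <= 1)).all()

    def test_no_divergence_mean_numerator_near_zero(self):
        cfg = TwoPopSimConfig(n_sites=20_000, divergence_F=0.0, seed=3)
        mat, _ = simulate_two_population(cfg)
        g = mat.group_indices()
        a, _, _, d = wc_fst_components(mat.calls, g["pop1"], g["pop2"])
        assert abs(np.nanmean(a[d])) < 5e-4

    def test_high_divergence_fst_near_one(self):
        cfg = TwoPopSimConfig(n_sites=5_000, divergence_F=0.9, seed=4)
        mat, _ = simulate_two_population(cfg)
        g = mat.group_indices()
        a, b, c, _ = wc_fst_components(mat.calls, g["pop1"], g["pop2"])
        assert fst_from_components(a, b, c) > 0.8

    @pytest.mark.parametrize("F", [0.05, 0.15, 0.30])
    def test_balding_nichols_recovery(self, F):
        cfg = TwoPopSimConfig(n_sites=10_000, divergence_F=F, seed=17)
        mat, _ = simulate_two_population(cfg)
        g = mat.group_indices()
        a, b, c, _ = wc_fst_components(mat.calls, g["pop1"], g["pop2"])
        assert fst_from_components(a, b, c) == pytest.approx(F, abs=0.02)

    def test_sweep_windows_lose_diversity_sign_test(self):
        from conftest import brute_force_pi_sum  # noqa: F401 (import check)
        from walnutkit.stats import site_pi_terms

        wins = 0
        for seed in range(20):
            cfg = TwoPopSimConfig(
                n_sites=2_000,
                chrom_length=2_000_000,
                divergence_F=0.15,
                sweep_windows=((0, 500_000),),
                sweep_pop="pop1",
                seed=seed,
            )
            mat, _ = simulate_two_population(cfg)
            g = mat.group_indices()
            in_sweep = (mat.positions - 1) < 500_000
            pi_terms, _ = site_pi_terms(mat.calls[:, g["pop1"]])
            sweep_pi = pi_terms[in_sweep].sum() / 500_000
            neutral_pi = pi_terms[~in_sweep].sum() / 1_500_000
            wins += sweep_pi < neutral_pi
        assert binomtest(wins, 20, 0.5, alternative="greater").pvalue < 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TwoPopSimConfig(n_pop1=1)
        with pytest.raises(ValueError):
            TwoPopSimConfig(divergence_F=1.0)
        with pytest.raises(ValueError):
            TwoPopSimConfig(sweep_windows=((-5, 100),))

    def test_empty_sites_warns(self):
        with pytest.warns(UserWarning):
            mat, _ = simulate_two_population(TwoPopSimConfig(n_sites=0, seed=0))
        assert mat.n_sites == 0


TRIO = {"f": (None, None), "m": (None, None), "kid": ("f", "m")}


class TestGeneDrop:
    def test_zero_length_map_copies_parent_haplotypes(self):
        gmap = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(5)], "lg": "c",
             "cm": [0.0] * 5, "bp": np.arange(1, 6) * 1000}
        )
        phased, truth = simulate_pedigree_genotypes(Pedigree(TRIO), gmap, seed=0)
        kid = phased["kid"]["c"]
        f, m = phased["f"]["c"], phased["m"]["c"]
        assert any(np.array_equal(kid[0], m[h]) for h in (0, 1))
        assert any(np.array_equal(kid[1], f[h]) for h in (0, 1))

    def test_poisson_crossover_rate_on_100cm_map(self):
        # one couple, many children: >=1000 meioses on a 100-cM chromosome
        ped = {"f": (None, None), "m": (None, None)}
        ped.update({f"k{i}": ("f", "m") for i in range(500)})
        rng_bp = np.linspace(1, 10_000_000, 21).astype(int)
        gmap = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(21)], "lg": "c",
             "cm": np.linspace(0, 100, 21), "bp": rng_bp}
        )
        _, truth = simulate_pedigree_genotypes(Pedigree(ped), gmap, seed=5)
        counts = [
            len(m["positions_cm"])
            for meioses in truth.crossovers.values()
            for m in meioses
        ]
        assert len(counts) >= 1000
        assert np.mean(counts) == pytest.approx(1.0, abs=0.1)

    def test_crossover_positions_strictly_increasing(self):
        gmap = uniform_genetic_map({"c": 5_000_000}, markers_per_mb=10, seed=2)
        ped = {"f": (None, None), "m": (None, None)}
        ped.update({f"k{i}": ("f", "m") for i in range(50)})
        _, truth = simulate_pedigree_genotypes(Pedigree(ped), gmap, seed=2)
        for meioses in truth.crossovers.values():
            for m in meioses:
                pos = m["positions_cm"]
                assert all(x < y for x, y in zip(pos, pos[1:]))

    def test_shared_ancestor_haplotypes_reach_both_parental_lines(self):
        # half-sib parents sharing one founder, as in the Chandler pedigree
        ped = Pedigree(
            {
                "Payne": (None, None), "CM": (None, None), "PI": (None, None),
                "Pedro": ("CM", "Payne"), "P56": ("PI", "Payne"),
                "Chandler": ("P56", "Pedro"),
            }
        )
        gmap = uniform_genetic_map(
            {"Chr1": 20_000_000, "Chr2": 20_000_000}, markers_per_mb=5, seed=3
        )
        _, truth = simulate_pedigree_genotypes(ped, gmap, seed=7)
        payne = {
            truth.founder_haplotypes.index("Payne:h0"),
            truth.founder_haplotypes.index("Payne:h1"),
        }
        maternal = set()
        paternal = set()
        for lg in ("Chr1", "Chr2"):
            org = truth.origins["Chandler"][lg]
            maternal |= set(org[0].tolist())
            paternal |= set(org[1].tolist())
        assert maternal & payne and paternal & payne

    def test_single_known_parent_rejected(self):
        with pytest.raises(ValueError, match="both parents"):
            Pedigree({"f": (None, None), "kid": ("f", None)})

    def test_non_monotone_map_rejected(self):
        gmap = pd.DataFrame(
            {"marker": ["a", "b"], "lg": "c", "cm": [2.0, 1.0], "bp": [10, 20]}
        )
        with pytest.raises(ValueError, match="monotone"):
            simulate_pedigree_genotypes(Pedigree(TRIO), gmap, seed=0)


class TestAnchoringFixture:
    def test_noiseless_filter_keeps_all_and_recovers_truth(self):
        lens, gmap, aln, truth = simulate_anchoring_fixture(
            n_scaffolds=5, markers_per_scaffold=6, decoy_fraction=0.0, seed=1
        )
        retained = filter_probe_alignments(aln)
        assert len(retained) == len(aln)
        anchored, unanchored = assign_order_orient(retained, gmap, lens)
        assert not unanchored
        order = [a.scaffold for a in sorted(anchored, key=lambda a: a.order_key)]
        assert order == truth.order["LG01"]
        assert all(
            a.orientation == truth.orientation[a.scaffold] for a in anchored
        )

    def test_decoys_removed_exactly(self):
        _, _, aln, truth = simulate_anchoring_fixture(
            n_scaffolds=6, markers_per_scaffold=8, decoy_fraction=0.2, seed=5
        )
        retained = filter_probe_alignments(aln)
        removed = set(aln["probe"]) - set(retained["probe"])
        assert removed == set(truth.decoy_probes)

    def test_two_scaffolds_opposite_orientation_reported(self):
        for seed in range(20):
            lens, gmap, aln, truth = simulate_anchoring_fixture(
                n_scaffolds=2, markers_per_scaffold=6, seed=seed
            )
            if len(set(truth.orientation.values())) == 2:
                break
        anchored, _ = assign_order_orient(filter_probe_alignments(aln), gmap, lens)
        assert {a.orientation for a in anchored} == {"+", "-"}
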