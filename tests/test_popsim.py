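"""Population simulator: recombination model, drift, LD build-up, breeding."""

import numpy as np
import pytest

from pigsurv.config import BreedingConfig, GenomeConfig, HistoryConfig
from pigsurv.popsim import (
    InsufficientParentsError,
    MarkerMap,
    breed_generation,
    found_base_population,
    make_marker_map,
    meiosis,
    simulate_history,
)

from conftest import two_locus_map


def _het_parent(n_loci: int) -> np.ndarray:
    """Phase-known doubly heterozygous parent: haplotypes all-0 / all-1."""
    return np.array([np.zeros(n_loci, np.uint8), np.ones(n_loci, np.uint8)])


class TestMarkerMap:
    def test_layout_counts_and_ordering(self, rng):
        g = GenomeConfig(n_chr=3, markers_per_chr=40, qtl_per_chr=7)
        mmap = make_marker_map(g, rng)
        assert mmap.n_loci == 3 * 47
        for c in (1, 2, 3):
            sel = mmap.chrom == c
            assert (~mmap.is_qtl[sel]).sum() == 40
            assert mmap.is_qtl[sel].sum() == 7
            assert np.all(np.diff(mmap.pos_cm[sel]) > 0)

    def test_non_increasing_positions_rejected(self):
        with pytest.raises(ValueError):
            MarkerMap(
                chrom=np.array([1, 1]),
                pos_cm=np.array([5.0, 5.0]),
                is_qtl=np.array([False, False]),
                ids=np.array(["a", "b"], dtype=object),
            )


class TestMeiosis:
    def test_zero_length_map_copies_one_parental_haplotype(self, rng):
        mmap = MarkerMap(
            chrom=np.array([1]),
            pos_cm=np.array([0.0]),
            is_qtl=np.array([False]),
            ids=np.array(["m0"], dtype=object),
        )
        parent = np.array([[0], [1]], dtype=np.uint8)
        gametes = {int(meiosis(rng, parent, mmap)[0]) for _ in range(50)}
        assert gametes == {0, 1}  # whole-haplotype copies, both chosen

    @pytest.mark.parametrize(
        "distance_cm,expected",
        [
            (100.0, (1.0 - np.exp(-2.0)) / 2.0),  # Haldane at 1 Morgan: 0.4323
            (0.01, (1.0 - np.exp(-0.0002)) / 2.0),  # small-distance limit 1e-4
        ],
    )
    def test_haldane_recombinant_fraction(self, distance_cm, expected):
        rng = np.random.default_rng(99)
        mmap = two_locus_map(distance_cm)
        parent = _het_parent(2)
        n = 40_000
        rec = 0
        for _ in range(n):
            g = meiosis(rng, parent, mmap)
            rec += g[0] != g[1]
        se = np.sqrt(expected * (1 - expected) / n) if expected > 1e-3 else 1e-4
        assert abs(rec / n - expected) < max(4 * se, 2e-4)

    def test_gamete_alleles_come_from_parent(self, rng):
        g = GenomeConfig(n_chr=2, markers_per_chr=30, qtl_per_chr=5)
        mmap = make_marker_map(g, rng)
        parent = (rng.random((2, mmap.n_loci)) < 0.5).astype(np.uint8)
        for _ in range(20):
            gam = meiosis(rng, parent, mmap)
            assert np.all((gam == parent[0]) | (gam == parent[1]))


class TestHistory:
    def test_zero_generations_returns_founder_law(self, rng):
        g = GenomeConfig(n_chr=2, markers_per_chr=200, qtl_per_chr=20)
        mmap = make_marker_map(g, rng)
        cfg = HistoryConfig(
            n_founder_males=50, n_founder_females=50, n_generations=0
        )
        haps, sexes, summary = simulate_history(mmap, cfg, rng)
        freqs = haps.sum(axis=(0, 1)) / (2 * 100)
        assert abs(freqs.mean() - 0.5) < 0.01  # founder initialisation at 0.5
        assert summary["n_segregating_markers"] == 400  # all segregate at n=100
        assert list(sexes[:50]) == ["M"] * 50

    def test_heterozygosity_drift_decay_matches_closed_form(self):
        # E[H_t] = H_0 (1 - 1/(2N))^t for neutral loci without mutation;
        # many chromosomes keep loci nearly independent, seeds are averaged
        N, t = 20, 15
        hets = []
        for seed in (5, 6, 7):
            rng = np.random.default_rng(seed)
            g = GenomeConfig(n_chr=12, markers_per_chr=30, qtl_per_chr=1)
            mmap = make_marker_map(g, rng)
            cfg = HistoryConfig(
                n_founder_males=N // 2,
                n_founder_females=N // 2,
                n_generations=t,
                mutation_rate=0.0,
            )
            haps, _, _ = simulate_history(mmap, cfg, rng)
            p = haps.sum(axis=(0, 1)) / (2 * N)
            hets.append(np.mean(2 * p * (1 - p)))
        expected = 2 * 0.5 * 0.5 * (1 - 1 / (2 * N)) ** t
        assert abs(np.mean(hets) - expected) / expected < 0.08

    def test_ld_grows_with_historical_generations(self):
        # brute-force r^2 between adjacent markers from haplotype counts
        def mean_adjacent_r2(n_gen, seed):
            rng = np.random.default_rng(seed)
            g = GenomeConfig(n_chr=1, markers_per_chr=60, qtl_per_chr=4)
            mmap = make_marker_map(g, rng)
            cfg = HistoryConfig(
                n_founder_males=15, n_founder_females=15, n_generations=n_gen
            )
            haps, _, _ = simulate_history(mmap, cfg, rng)
            H = haps.reshape(-1, mmap.n_loci).astype(float)  # gametes x loci
            mk = mmap.marker_idx
            r2s = []
            for a, b in zip(mk[:-1], mk[1:]):
                pa, pb = H[:, a].mean(), H[:, b].mean()
                if not (0 < pa < 1 and 0 < pb < 1):
                    continue
                pab = (H[:, a] * H[:, b]).mean()
                D = pab - pa * pb
                r2s.append(D * D / (pa * (1 - pa) * pb * (1 - pb)))
            return float(np.mean(r2s))
        assert mean_adjacent_r2(100, seed=42) > mean_adjacent_r2(2, seed=42)


def _mini_setup(seed=3, n_sires=3, base_sows=40):
    rng = np.random.default_rng(seed)
    g = GenomeConfig(n_chr=2, markers_per_chr=25, qtl_per_chr=5)
    mmap = make_marker_map(g, rng)
    hist = HistoryConfig(n_founder_males=20, n_founder_females=50, n_generations=2)
    haps, sexes, _ = simulate_history(mmap, hist, rng)
    breeding = BreedingConfig(
        n_sires=n_sires, n_dams=n_sires * 10, dams_per_sire=10,
        base_boars=n_sires, base_sows=base_sows,
    )
    return rng, mmap, haps, sexes, breeding


class TestBasePopulation:
    def test_base_counts_and_sexes(self):
        rng, mmap, haps, sexes, breeding = _mini_setup()
        state = found_base_population(haps, sexes, mmap, breeding, rng)
        ped = state.pedigree
        assert len(ped) == 3 + 40
        assert (ped["sex"] == "M").sum() == 3
        assert (ped["generation"] == 0).all()
        assert (ped[["sire", "dam"]] == 0).all().all()

    def test_full_selection_is_identity(self, rng):
        _, mmap, haps, sexes, _ = _mini_setup()
        breeding = BreedingConfig(
            n_sires=2, n_dams=20, dams_per_sire=10, base_boars=20, base_sows=50
        )
        state = found_base_population(haps, sexes, mmap, breeding, rng)
        # every historical animal selected: haplotypes carried over verbatim
        assert state.haplotypes.shape[0] == 70
        assert np.array_equal(
            np.sort(state.haplotypes.sum(axis=(1, 2))),
            np.sort(haps.sum(axis=(1, 2))),
        )

    def test_same_seed_same_base(self):
        _, mmap, haps, sexes, breeding = _mini_setup()
        s1 = found_base_population(haps, sexes, mmap, breeding, np.random.default_rng(7))
        s2 = found_base_population(haps, sexes, mmap, breeding, np.random.default_rng(7))
        assert s1.pedigree.equals(s2.pedigree)
        assert np.array_equal(s1.haplotypes, s2.haplotypes)

    def test_insufficient_candidates_raises(self):
        rng, mmap, haps, sexes, _ = _mini_setup()
        breeding = BreedingConfig(
            n_sires=2, n_dams=20, dams_per_sire=10, base_boars=21, base_sows=10
        )
        with pytest.raises(InsufficientParentsError):
            found_base_population(haps, sexes, mmap, breeding, rng)


class TestBreeding:
    def test_litter_law_expectation_is_14(self):
        b = BreedingConfig()
        assert b.expected_litter_size == pytest.approx(14.0)

    def test_degenerate_litter_law_gives_constant_litters(self):
        rng, mmap, haps, sexes, _ = _mini_setup()
        breeding = BreedingConfig(
            n_sires=3, n_dams=30, dams_per_sire=10, base_boars=3, base_sows=40,
            litter_probs=(0.0, 0.0, 1.0, 0.0, 0.0),
        )
        state = found_base_population(haps, sexes, mmap, breeding, rng)
        breed_generation(state, breeding, rng)
        gen1 = state.pedigree[state.pedigree["generation"] == 1]
        assert (gen1.groupby("litter").size() == 14).all()

    def test_mating_design_each_sire_10_dams_each_dam_one_litter(self):
        rng, mmap, haps, sexes, breeding = _mini_setup(base_sows=40)
        state = found_base_population(haps, sexes, mmap, breeding, rng)
        breed_generation(state, breeding, rng)  # gen 1 (uses all 40 sows? 30 dams)
        gen1 = state.pedigree[state.pedigree["generation"] == 1]
        per_litter = gen1.groupby("litter")
        assert per_litter["dam"].nunique().eq(1).all()
        assert gen1.groupby("dam")["litter"].nunique().eq(1).all()
        assert gen1["dam"].nunique() == 30
        sire_dams = gen1.groupby("sire")["dam"].nunique()
        assert sorted(sire_dams) == [10, 10, 10]

    def test_mendelian_consistency_exhaustive(self):
        rng, mmap, haps, sexes, breeding = _mini_setup(base_sows=40)
        state = found_base_population(haps, sexes, mmap, breeding, rng)
        breed_generation(state, breeding, rng)
        ped = state.pedigree
        for _, row in ped[ped["generation"] == 1].head(60).iterrows():
            child = state.haplotypes[int(row["id"]) - 1]
            for hap_idx, parent in ((0, "sire"), (1, "dam")):
                ph = state.haplotypes[int(row[parent]) - 1]
                g = child[hap_idx]
                assert np.all((g == ph[0]) | (g == ph[1]))

    def test_insufficient_alive_parents_raises(self):
        rng, mmap, haps, sexes, breeding = _mini_setup(base_sows=40)
        state = found_base_population(haps, sexes, mmap, breeding, rng)
        breed_generation(state, breeding, rng)
        # kill every generation-1 female: next breeding must fail
        g1 = state.pedigree["generation"] == 1
        state.pedigree.loc[g1 & (state.pedigree["sex"] == "F"), "alive"] = 0
        with pytest.raises(InsufficientParentsError):
            breed_generation(state, breeding, rng)

    def test_generations_do_not_overlap(self):
        rng, mmap, haps, sexes, breeding = _mini_setup(base_sows=40)
        state = found_base_population(haps, sexes, mmap, breeding, rng)
        for _ in range(3):
            breed_generation(state, breeding, rng)
        ped = state.pedigree.set_index("id")
        gen = ped["generation"]
        parents = ped.loc[ped["generation"] > 0, ["sire", "dam"]]
        # each parent belongs to the generation immediately before its offspring
        for col in ("sire", "dam"):
            assert (
                gen.loc[parents[col]].to_numpy()
                == gen.loc[parents.index].to_numpy() - 1
            ).all()
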