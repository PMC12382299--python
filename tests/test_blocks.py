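import numpy as np
import pandas as pd
import pytest

from _simtools import brute_force_blocks, founder_panel
from testcross_gwas.blocks import (HaplotypeBlock, allele_effect_range, build_blocks,
                                   build_blocks_genome, enumerate_alleles, flag_blocks,
                                   pairwise_ld)


def ld_frame(mat, prefix="m"):
    ids = [f"{prefix}{i + 1}" for i in range(len(mat))]
    return pd.DataFrame(np.asarray(mat, float), index=ids, columns=ids)


def map_for(ld, chrom="A01"):
    return pd.DataFrame({"chromosome": chrom, "pos": [100 * (i + 1) for i in range(len(ld))]},
                        index=ld.index)


class TestPairwiseLD:
    def test_identical_columns_r2_one(self):
        d = pd.DataFrame({"a": [0, 0, 2, 2.0], "b": [0, 0, 2, 2.0]})
        assert pairwise_ld(d).loc["a", "b"] == pytest.approx(1.0)

    def test_orthogonal_columns_r2_zero(self):
        d = pd.DataFrame({"a": [0, 0, 2, 2.0], "b": [0, 2, 0, 2.0]})
        assert pairwise_ld(d).loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_third(self):
        d = pd.DataFrame({"a": [0, 0, 2, 2.0], "b": [0, 2, 2, 2.0]})
        assert pairwise_ld(d).loc["a", "b"] == pytest.approx(1.0 / 3.0)

    def test_constant_marker_convention(self):
        d = pd.DataFrame({"a": [2, 2, 2, 2.0], "b": [0, 2, 0, 2.0]})
        ld = pairwise_ld(d)
        assert ld.loc["a", "b"] == 0.0 and ld.loc["a", "a"] == 1.0

    def test_bounds_and_symmetry(self, small_bundle):
        geno = small_bundle["geno"]
        chrom1 = geno.marker_map.index[geno.marker_map["chromosome"] == "A01"]
        ld = pairwise_ld(geno.dosages[list(chrom1)]).to_numpy()
        assert ld.min() >= 0 and ld.max() <= 1
        assert np.allclose(ld, ld.T)
        assert np.allclose(np.diag(ld), 1.0)


class TestBuildBlocks:
    def test_chain_without_tolerance(self):
        # adjacent r2: 0.9, 0.5, 0.2 -> block of the first three markers
        ld = ld_frame([[1.0, 0.9, 0.0, 0.0],
                       [0.9, 1.0, 0.5, 0.0],
                       [0.0, 0.5, 1.0, 0.2],
                       [0.0, 0.0, 0.2, 1.0]])
        blocks = build_blocks(ld, map_for(ld), r2_min=0.4, tolerance=0)
        assert [b.markers for b in blocks] == [["m1", "m2", "m3"]]

    def test_tolerated_marker_absorbed(self):
        # m3 fails against the edge (0.1) but m4 conforms (0.8): m3 absorbed
        ld = ld_frame([[1.0, 0.9, 0.0, 0.0],
                       [0.9, 1.0, 0.1, 0.8],
                       [0.0, 0.1, 1.0, 0.0],
                       [0.0, 0.8, 0.0, 1.0]])
        blocks = build_blocks(ld, map_for(ld), r2_min=0.4, tolerance=1)
        assert [b.markers for b in blocks] == [["m1", "m2", "m3", "m4"]]

    def test_no_admissible_seed(self):
        ld = ld_frame([[1.0, 0.3, 0.1],
                       [0.3, 1.0, 0.2],
                       [0.1, 0.2, 1.0]])
        assert build_blocks(ld, map_for(ld), r2_min=0.4, tolerance=0) == []

    def test_vacuous_threshold_single_block(self):
        rng = np.random.default_rng(0)
        m = rng.random((6, 6))
        ld = ld_frame((m + m.T) / 2)
        blocks = build_blocks(ld, map_for(ld), r2_min=0.0, tolerance=0)
        assert len(blocks) == 1 and blocks[0].markers == list(ld.index)

    def test_leftmost_tie_break(self):
        ld = ld_frame([[1.0, 0.8, 0.0, 0.0],
                       [0.8, 1.0, 0.0, 0.0],
                       [0.0, 0.0, 1.0, 0.8],
                       [0.0, 0.0, 0.8, 1.0]])
        blocks = build_blocks(ld, map_for(ld), r2_min=0.4, tolerance=0)
        assert blocks[0].markers == ["m1", "m2"]  # leftmost pair seeds first

    def test_span_and_ids(self):
        ld = ld_frame([[1.0, 0.9], [0.9, 1.0]])
        mp = pd.DataFrame({"chromosome": "A03", "pos": [1_000, 5_008_140]}, index=ld.index)
        b = build_blocks(ld, mp, id_offset=2)[0]
        assert b.id == "b000003" and b.span_kbp == 5007.14

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_replay(self, seed):
        """The production builder reproduces a literal replay of the
        seeding/extension/tolerance rules on random LD matrices."""
        rng = np.random.default_rng(seed)
        M = rng.integers(2, 13)
        a = rng.random((M, M))
        sym = (a + a.T) / 2
        np.fill_diagonal(sym, 1.0)
        ld = ld_frame(sym)
        tol = int(rng.integers(0, 4))
        blocks = build_blocks(ld, map_for(ld), r2_min=0.4, tolerance=tol)
        got = sorted([list(ld.index).index(m) for m in b.markers] for b in blocks)
        want = brute_force_blocks(sym.tolist(), 0.4, tol)
        assert got == want

    def test_blocks_partition_contiguously(self, small_bundle):
        geno = small_bundle["geno"]
        blocks = build_blocks_genome(geno.dosages, geno.marker_map)
        seen = set()
        order = list(geno.marker_map.index)
        for b in blocks:
            assert not (seen & set(b.markers))  # no marker in two blocks
            seen.update(b.markers)
            idx = [order.index(m) for m in b.markers]
            assert idx == list(range(min(idx), max(idx) + 1))  # contiguous

    def test_raising_threshold_shrinks_coverage(self, small_bundle):
        geno = small_bundle["geno"]
        assigned = []
        for r2_min in (0.2, 0.4, 0.6, 0.8):
            blocks = build_blocks_genome(geno.dosages, geno.marker_map, r2_min=r2_min)
            assigned.append(sum(b.n_markers for b in blocks))
        assert assigned == sorted(assigned, reverse=True)

    def test_independent_of_marker_names(self, small_bundle):
        geno = small_bundle["geno"]
        chrom1 = list(geno.marker_map.index[geno.marker_map["chromosome"] == "A01"])
        ld = pairwise_ld(geno.dosages[chrom1])
        blocks1 = build_blocks(ld, geno.marker_map)
        renames = {m: f"zz_{i:03d}" for i, m in enumerate(chrom1)}
        ld2 = ld.rename(index=renames, columns=renames)
        mp2 = geno.marker_map.loc[chrom1].rename(index=renames)
        blocks2 = build_blocks(ld2, mp2)
        spans1 = [(b.start_bp, b.end_bp) for b in blocks1]
        spans2 = [(b.start_bp, b.end_bp) for b in blocks2]
        assert spans1 == spans2


class TestFlagBlocks:
    def make(self):
        b1 = HaplotypeBlock("b000001", "A01", ["m1", "m2"], 100, 200)
        b2 = HaplotypeBlock("b000002", "A01", ["m3", "m4"], 300, 400)
        gwas = pd.DataFrame({
            "trait": ["t1", "t1", "t1", "t2", "t1"],
            "marker": ["m1", "m2", "m3", "m3", "m9"],
            "p": [5e-4, 0.5, 2e-3, 8e-4, 1e-5],
        })
        return [b1, b2], gwas

    def test_member_below_threshold_flags_block(self):
        blocks, gwas = self.make()
        out, _ = flag_blocks(blocks, gwas)
        assert out[0].significant and out[0].traits == ["t1"]

    def test_min_p_above_threshold_not_flagged_for_trait(self):
        blocks, gwas = self.make()
        out, _ = flag_blocks(blocks, gwas)
        assert "t1" not in out[1].traits  # min p for t1 in b2 is 2e-3
        assert out[1].traits == ["t2"]

    def test_singletons_reported(self):
        blocks, gwas = self.make()
        _, singles = flag_blocks(blocks, gwas)
        assert list(singles["marker"]) == ["m9"]


class TestAlleles:
    def test_biallelic_single_marker_block(self):
        geno, _ = founder_panel(30, 20, seed=4)
        block = HaplotypeBlock("b000001", "A01", [geno.markers[0]], 100, 100)
        values = pd.DataFrame({"father": geno.ids,
                               "trait": np.zeros(len(geno.ids))})
        alleles = enumerate_alleles(block, geno.dosages, values, min_carriers=1)
        labelled = [a for a in alleles if a.pattern is not None]
        assert len(labelled) == 2
        assert {a.pattern for a in labelled} == {(0,), (2,)}

    def test_planted_founder_patterns_recovered(self):
        """Distinct founder patterns planted over a 4-marker block are all
        enumerated with the correct carrier lists."""
        rng = np.random.default_rng(8)
        patterns = [tuple(rng.choice([0, 2], 4)) for _ in range(12)]
        patterns = list(dict.fromkeys(patterns))[:10]
        fathers = []
        rows = []
        for i, pat in enumerate(patterns):
            for c in range(3):  # 3 carriers each
                fathers.append(f"F{i}_{c}")
                rows.append(pat)
        dosages = pd.DataFrame(rows, index=fathers,
                               columns=[f"m{j}" for j in range(4)], dtype=float)
        block = HaplotypeBlock("b000001", "A01", list(dosages.columns), 0, 300)
        values = pd.DataFrame({"father": fathers, "trait": 0.0})
        alleles = enumerate_alleles(block, dosages, values, min_carriers=3)
        labelled = [a for a in alleles if a.pattern is not None]
        assert {a.pattern for a in labelled} == set(patterns)

    def test_rare_and_incomplete_bins(self):
        dosages = pd.DataFrame({"m1": [0, 0, 0, 2, np.nan],
                                "m2": [0, 0, 0, 2, 2]},
                               index=[f"F{i}" for i in range(5)], dtype=float)
        block = HaplotypeBlock("b000001", "A01", ["m1", "m2"], 0, 100)
        values = pd.DataFrame({"father": dosages.index, "trait": 1.0})
        alleles = enumerate_alleles(block, dosages, values, min_carriers=3)
        labels = {a.label: a for a in alleles}
        assert labels["1"].carriers == ["F0", "F1", "F2"]
        assert labels["rare"].carriers == ["F3"]
        assert labels["incomplete"].carriers == ["F4"]

    def test_planted_allele_effect_recovered(self):
        """A planted mean difference between carriers of two block alleles
        is recovered within 3 standard errors."""
        rng = np.random.default_rng(15)
        n_per = 40
        fathers = [f"F{i:03d}" for i in range(2 * n_per)]
        dosages = pd.DataFrame(
            {"m1": [0.0] * n_per + [2.0] * n_per,
             "m2": [0.0] * n_per + [2.0] * n_per},
            index=fathers)
        delta, sd = 2.0, 1.0
        vals = np.r_[rng.normal(0, sd, n_per), rng.normal(delta, sd, n_per)]
        block = HaplotypeBlock("b000001", "A01", ["m1", "m2"], 0, 100)
        values = pd.DataFrame({"father": fathers, "trait": vals})
        alleles = enumerate_alleles(block, dosages, values)
        rng_est = allele_effect_range(alleles, "trait")
        se = sd * np.sqrt(2.0 / n_per)
        assert abs(rng_est - delta) < 3 * se
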