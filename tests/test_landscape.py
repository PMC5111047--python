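import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from termeth.io import AnnotationSet, GeneModel, GenomeAssembly
from termeth.landscape import (
    cpg_oe,
    gc_content,
    junction_profile,
    metagene_profile,
    methylation_deciles,
    nearest_gene_distance,
    ortholog_methylation_classes,
    promoter_island_profile,
    repeat_context_methylation,
)
from termeth.simulate import SimulationDesign, simulate_genome


def sites(positions, fractions, scaffold="s", status=None):
    df = pd.DataFrame({"scaffold": scaffold, "pos": positions,
                       "fraction": fractions})
    df["m"] = (df["fraction"] * 20).round().astype(int)
    df["u"] = 20 - df["m"]
    if status is not None:
        df["status"] = status
    return df


class TestCpgOe:
    @pytest.mark.parametrize(
        "seq,expected",
        [("CGCG", 2.0), ("ACGT", 4.0), ("CCCC", np.nan), ("AATT", np.nan)],
    )
    def test_known_values(self, seq, expected):
        got = cpg_oe(seq)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_gc_content(self):
        assert gc_content("ACGT") == 0.5

    def test_depletion_tracks_historical_methylation(self):
        # forward simulation of deamination-driven CpG loss: genes with
        # higher historical methylation lose more CpGs, so CpG o/e falls
        rng = np.random.default_rng(8)
        pis = rng.uniform(0, 1, 500)
        oes = []
        for pi in pis:
            seq = list("".join(rng.choice(list("ACGT"), size=2000)))
            for m in list(re.finditer("CG", "".join(seq))):
                if rng.random() < 0.8 * pi:
                    seq[m.start()] = "T"
            oes.append(cpg_oe("".join(seq)))
        rho = stats.spearmanr(pis, oes).statistic
        assert rho < -0.5


class TestMetagene:
    def test_uniform_fraction_gives_flat_profile(self):
        g = GeneModel("g", "s", "+", [(1000, 3000)])
        s = sites(np.arange(500, 3500, 10), 0.5)
        prof = metagene_profile(s, [g], n_bins=10, flank_bp=500, flank_bins=5)
        assert np.allclose(prof["mean_fraction"], 0.5)

    def test_minus_strand_gene_mirrors_plus(self):
        gradient = np.linspace(0.1, 0.9, 200)
        pos = np.arange(1000, 3000, 10)
        plus = metagene_profile(sites(pos, gradient),
                                [GeneModel("p", "s", "+", [(1000, 3000)])],
                                n_bins=10, flank_bp=0, flank_bins=1)
        minus = metagene_profile(sites(pos, gradient[::-1]),
                                 [GeneModel("m", "s", "-", [(1000, 3000)])],
                                 n_bins=10, flank_bp=0, flank_bins=1)
        body_p = plus[(plus["bin"] >= 0) & (plus["bin"] < 10)]
        body_m = minus[(minus["bin"] >= 0) & (minus["bin"] < 10)]
        assert np.allclose(body_p["mean_fraction"], body_m["mean_fraction"])

    def test_gradient_recovered_monotonically(self):
        pos = np.arange(1000, 3000, 5)
        gradient = np.linspace(0.05, 0.95, len(pos))
        prof = metagene_profile(sites(pos, gradient),
                                [GeneModel("g", "s", "+", [(1000, 3000)])],
                                n_bins=20, flank_bp=0, flank_bins=1)
        body = prof[(prof["bin"] >= 0) & (prof["bin"] < 20)]
        rho = stats.spearmanr(body["bin"], body["mean_fraction"]).statistic
        assert rho > 0.99

    def test_bad_bins(self):
        with pytest.raises(ValueError):
            metagene_profile(sites([1], [0.5]), [], n_bins=0)


class TestJunctions:
    def test_uniform_methylome_flat_on_both_sides(self):
        g = GeneModel("g", "s", "+", [(0, 500), (800, 1300)])
        s = sites(np.arange(0, 1300, 7), 0.6)
        prof = junction_profile(s, [g], span_bp=100)
        assert np.allclose(prof["mean_fraction"], 0.6)

    def test_single_exon_gene_contributes_nothing(self):
        g = GeneModel("g", "s", "+", [(0, 500)])
        prof = junction_profile(sites(np.arange(0, 500, 5), 0.5), [g])
        assert len(prof) == 0

    def test_planted_step_recovered(self):
        g = GeneModel("g", "s", "+", [(0, 500), (800, 1300)])
        pos = np.arange(0, 1300, 3)
        in_exon = (pos < 500) | (pos >= 800)
        frac = np.where(in_exon, 0.8, 0.6)
        prof = junction_profile(sites(pos, frac), [g], span_bp=150)
        exon_side = prof[prof["offset"] < 0]["mean_fraction"].mean()
        intron_side = prof[prof["offset"] >= 0]["mean_fraction"].mean()
        assert exon_side - intron_side == pytest.approx(0.2, abs=0.02)


class TestDeciles:
    def test_twenty_genes_two_per_decile(self):
        f = pd.Series(np.linspace(0, 1, 20), index=[f"g{i}" for i in range(20)])
        d = methylation_deciles(f)
        assert d.value_counts().eq(2).all()

    def test_ties_keep_equal_sizes(self):
        f = pd.Series(0.5, index=[f"g{i:02d}" for i in range(23)])
        d = methylation_deciles(f)
        assert d.value_counts().max() - d.value_counts().min() <= 1

    def test_top3_decile_count_reconstruction(self):
        # 10,240 ranked genes -> the top 3 deciles hold 3,072 genes
        f = pd.Series(np.arange(10240), index=[f"g{i:05d}" for i in range(10240)])
        d = methylation_deciles(f)
        assert int((d >= 8).sum()) == 3072

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValueError):
            methylation_deciles(pd.Series([0.1] * 9))


class TestNearestGeneDistance:
    def test_two_genes_simple_gap(self):
        genes = [GeneModel("a", "s", "+", [(0, 100)]),
                 GeneModel("b", "s", "+", [(150, 200)])]
        d = nearest_gene_distance(genes)
        assert d["a"] == 50 and d["b"] == 50

    def test_overlapping_genes_distance_zero(self):
        genes = [GeneModel("a", "s", "+", [(0, 100)]),
                 GeneModel("b", "s", "+", [(50, 200)])]
        assert nearest_gene_distance(genes).eq(0).all()

    def test_lonely_gene_missing(self):
        genes = [GeneModel("a", "s", "+", [(0, 100)])]
        assert np.isnan(nearest_gene_distance(genes)["a"])

    def test_clustered_methylated_genes_are_closer(self):
        d = SimulationDesign(seed=11, n_genes=40, n_scaffolds=2,
                             scaffold_len=200_000, cluster_factor=1.0)
        _, ann, truth = simulate_genome(d)
        dist = nearest_gene_distance(ann.genes)
        g = truth["genes"].set_index("gene")
        meth = dist[g["methylated"].reindex(dist.index)]
        un = dist[~g["methylated"].reindex(dist.index)]
        p = stats.mannwhitneyu(meth.dropna(), un.dropna(),
                               alternative="less").pvalue
        assert p < 0.05


class TestPromoterIsland:
    def _island_setup(self):
        # methylated gene with a CpG-dense unmethylated promoter
        rng = np.random.default_rng(0)
        body = "".join(rng.choice(list("ACGT"), size=4000))
        promoter = "CG" * 250
        seq = body[:2000] + promoter + body[2000:]
        genome = GenomeAssembly({"s": seq})
        gene = GeneModel("g", "s", "+", [(2500, 4500)], promoter=(2000, 2500))
        pos = np.arange(500, 6000, 9)
        in_prom = (pos >= 2000) & (pos < 2500)
        frac = np.where(in_prom, 0.0, 0.8)
        status = np.where(in_prom, "unmethylated", "methylated")
        return genome, gene, sites(pos, frac, status=status)

    def test_island_contrast_recovered(self):
        genome, gene, s = self._island_setup()
        prof = promoter_island_profile(s, [gene], genome, span_bp=1500, n_bins=30)
        mid = prof[(prof["bin"] >= 12) & (prof["bin"] < 18)]
        edge = prof[(prof["bin"] < 5) | (prof["bin"] >= 25)]
        assert mid["meth_fraction"].mean() < edge["meth_fraction"].mean()
        assert mid["cpg_oe"].mean() > edge["cpg_oe"].mean()

    def test_methylated_promoter_excluded(self):
        genome, gene, s = self._island_setup()
        s.loc[:, "status"] = "methylated"  # promoter methylated too
        with pytest.warns(UserWarning, match="no qualifying"):
            prof = promoter_island_profile(s, [gene], genome)
        assert len(prof) == 0


class TestRepeatContext:
    def _annotation(self):
        genes = [GeneModel(f"g{i}", "s", "+", [(i * 2000, i * 2000 + 1000)])
                 for i in range(50)]
        return AnnotationSet(genes)

    def test_repeat_with_two_cpgs_excluded(self):
        ann = self._annotation()
        s = sites([10, 20], [0.5, 0.5])
        out = repeat_context_methylation(s, [("s", 0, 30, "r")], ann)
        assert out["n_repeats"].sum() == 0

    def test_planted_hypomethylated_exonic_repeats(self):
        rng = np.random.default_rng(1)
        ann = self._annotation()
        pos, frac = [], []
        repeats = []
        for i in range(50):
            base = i * 2000
            repeats.append(("s", base + 100, base + 300, f"r{i}"))
            for p in range(base, base + 1000, 20):
                inside = base + 100 <= p < base + 300
                pos.append(p)
                frac.append(
                    np.clip(rng.normal(0.4 if inside else 0.8, 0.05), 0, 1)
                )
        out = repeat_context_methylation(sites(pos, frac), repeats, ann)
        ex = out[out["class"] == "exonic"].iloc[0]
        assert ex["repeat_mean"] < ex["context_mean"]
        assert ex["p"] < 0.01

    def test_equal_repeat_and_context_high_p(self):
        ann = self._annotation()
        pos = list(range(0, 1000, 20)) + list(range(2000, 3000, 20))
        repeats = [("s", 100, 300, "r1"), ("s", 2100, 2300, "r2")]
        out = repeat_context_methylation(sites(pos, [0.5] * len(pos)), repeats, ann)
        ex = out[out["class"] == "exonic"].iloc[0]
        assert ex["p"] > 0.5 or np.isnan(ex["p"])


class TestOrthologClasses:
    def _status(self):
        return pd.DataFrame(
            {
                "ortholog": ["o1", "o2", "o3"],
                "Znev": ["methylated", "methylated", "unmethylated"],
                "Cflo": ["unmethylated", "methylated", "unmethylated"],
                "Amel": ["unmethylated", "methylated", "unmethylated"],
            }
        )

    def test_class_labels(self):
        classes, summary = ortholog_methylation_classes(self._status())
        by = classes.set_index("ortholog")["class"]
        assert by["o1"] == "Znev-only"
        assert by["o2"] == "all"
        assert by["o3"] == "none"

    def test_counts_sum_to_complete_triplets(self):
        df = self._status()
        df.loc[3] = ["o4", "methylated", None, "methylated"]
        classes, summary = ortholog_methylation_classes(df)
        assert summary["n_orthologs"].sum() == 3
        assert summary.attrs["n_dropped_incomplete"] == 1

    def test_duplicate_ortholog_is_error(self):
        df = self._status()
        df.loc[3] = df.loc[0]
        with pytest.raises(ValueError, match="duplicate"):
            ortholog_methylation_classes(df)
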