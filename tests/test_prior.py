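"""Epigenomic prior network construction."""

import numpy as np
import pandas as pd
import pytest

import epigrn as eg
from epigrn import ValidationError


def _cpg_table(rows):
    return eg.CpGCountTable(pd.DataFrame(
        rows, columns=["chrom", "position", "count_methylated",
                       "count_unmethylated", "sample_id"]
    ))


def _regions(rows):
    return eg.RegionSet(pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end"]
    ))


class TestAggregateMethylation:
    def test_rate_and_coverage_at_threshold(self):
        cpgs = _cpg_table([("chr1", 110, 4, 6, "s1")])
        regions = _regions([("r1", "chr1", 100, 200)])
        sig = eg.aggregate_region_methylation(cpgs, regions, min_reads=10)
        assert sig.values.loc["r1", "s1"] == pytest.approx(0.4)
        assert bool(sig.coverage.loc["r1", "s1"]) is True

    def test_below_min_reads_uncovered(self):
        cpgs = _cpg_table([("chr1", 110, 4, 5, "s1")])  # 9 reads total
        regions = _regions([("r1", "chr1", 100, 200)])
        sig = eg.aggregate_region_methylation(cpgs, regions, min_reads=10)
        assert bool(sig.coverage.loc["r1", "s1"]) is False

    def test_fully_unmethylated_covered(self):
        cpgs = _cpg_table([("chr1", 110, 0, 12, "s1")])
        regions = _regions([("r1", "chr1", 100, 200)])
        sig = eg.aggregate_region_methylation(cpgs, regions, min_reads=10)
        assert sig.values.loc["r1", "s1"] == 0.0
        assert bool(sig.coverage.loc["r1", "s1"]) is True

    def test_multiple_cpgs_summed_before_ratio(self):
        cpgs = _cpg_table([
            ("chr1", 110, 2, 3, "s1"),
            ("chr1", 150, 6, 1, "s1"),
        ])
        regions = _regions([("r1", "chr1", 100, 200)])
        sig = eg.aggregate_region_methylation(cpgs, regions, min_reads=10)
        assert sig.values.loc["r1", "s1"] == pytest.approx(8 / 12)

    def test_empty_region_set_rejected(self):
        cpgs = _cpg_table([("chr1", 110, 2, 3, "s1")])
        with pytest.raises(Exception):
            eg.aggregate_region_methylation(
                cpgs,
                eg.RegionSet(pd.DataFrame(
                    columns=["region_id", "chrom", "start", "end"])),
            )

    def test_no_cpg_in_regions_warns(self):
        cpgs = _cpg_table([("chr2", 110, 2, 30, "s1")])
        regions = _regions([("r1", "chr1", 100, 200)])
        with pytest.warns(UserWarning, match="uncovered"):
            sig = eg.aggregate_region_methylation(cpgs, regions)
        assert not sig.coverage.to_numpy().any()


class TestMatchedRegions:
    @pytest.fixture
    def rankings(self):
        ranks = np.arange(1, 11)[None, :]
        return eg.MotifRankingMatrix(pd.DataFrame(
            ranks, index=["m1"], columns=[f"r{i}" for i in range(1, 11)]
        ))

    def test_full_fraction_returns_all(self, rankings):
        assert len(eg.matched_regions(rankings, "m1", top_frac=1.0)) == 10

    def test_ceiling_rule(self, rankings):
        assert eg.matched_regions(rankings, "m1", top_frac=0.2) == ["r1", "r2"]
        # ceil(1.5) = 2
        assert eg.matched_regions(rankings, "m1", top_frac=0.15) == ["r1", "r2"]

    def test_unknown_motif(self, rankings):
        with pytest.raises(ValidationError):
            eg.matched_regions(rankings, "nope")


class TestAssignRegionsToGenes:
    @pytest.fixture
    def tss(self):
        return eg.TssTable(pd.DataFrame({
            "gene_id": ["gA"], "chrom": ["chr1"], "tss": [10000],
            "strand": ["+"],
        }))

    def test_within_5kb_assigned(self, tss):
        rm = eg.assign_regions_to_genes(
            _regions([("r1", "chr1", 9500, 9700)]), tss
        )
        assert rm.as_dict()["r1"] == ("gA", 300)

    def test_beyond_5kb_dropped(self, tss):
        rm = eg.assign_regions_to_genes(
            _regions([("r1", "chr1", 20100, 20200)]), tss
        )
        assert len(rm) == 0

    def test_tss_inside_region_distance_zero(self, tss):
        rm = eg.assign_regions_to_genes(
            _regions([("r1", "chr1", 9900, 10100)]), tss
        )
        assert rm.as_dict()["r1"] == ("gA", 0)

    def test_tie_breaks_lexicographically(self):
        tss = eg.TssTable(pd.DataFrame({
            "gene_id": ["gB", "gA"], "chrom": ["chr1", "chr1"],
            "tss": [900, 1200], "strand": ["+", "+"],
        }))
        # region [1000,1100): distance to both TSS is 100
        rm = eg.assign_regions_to_genes(
            _regions([("r1", "chr1", 1000, 1100)]), tss
        )
        assert rm.as_dict()["r1"][0] == "gA"

    def test_empty_tss_rejected(self):
        with pytest.raises(ValidationError):
            eg.assign_regions_to_genes(
                _regions([("r1", "chr1", 0, 10)]),
                eg.TssTable(pd.DataFrame(
                    columns=["gene_id", "chrom", "tss", "strand"])),
            )


class TestBuildPriorMLC:
    def test_planted_peaks_retained(self):
        sim = eg.simulate_epigenome(
            n_regions=600, n_motifs=10, active_motifs=3, effect=2.0,
            mode="peaks", n_samples=5, seed=42,
        )
        res = eg.build_prior_mlc(sim.signal, sim.rankings, sim.regions,
                                 sim.tss)
        assert set(sim.active_motifs) <= set(res.retained_motifs)
        # retained motifs produce edges to promoter-adjacent genes
        assert res.network.n_edges > 0

    def test_minority_significance_not_retained(self):
        # motif significant in 1 of 3 samples under majority rule
        rng = np.random.default_rng(0)
        R = 60
        region_ids = [f"r{i}" for i in range(R)]
        ranks = eg.MotifRankingMatrix(pd.DataFrame(
            [rng.permutation(np.arange(1, R + 1))], index=["m1"],
            columns=region_ids,
        ))
        closeness = -ranks.ranks.loc["m1"].to_numpy()
        # sample s1 tracks the motif perfectly; s2, s3 are noise
        perfect = (closeness > np.median(closeness)).astype(float)
        vals = pd.DataFrame({
            "s1": perfect,
            "s2": rng.integers(0, 2, R).astype(float),
            "s3": rng.integers(0, 2, R).astype(float),
        }, index=region_ids)
        signal = eg.RegionSignalMatrix(values=vals, kind="binary")
        regions = _regions(
            [(r, "chr1", i * 20000, i * 20000 + 100)
             for i, r in enumerate(region_ids)]
        )
        tss = eg.TssTable(pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(R)], "chrom": "chr1",
            "tss": [i * 20000 + 200 for i in range(R)], "strand": "+",
        }))
        res = eg.build_prior_mlc(signal, ranks, regions, tss,
                                 sample_rule="majority")
        assert res.retained_motifs == []

    def test_alpha_zero_empty_prior(self):
        sim = eg.simulate_epigenome(
            n_regions=200, n_motifs=5, active_motifs=2, effect=2.0,
            mode="peaks", n_samples=3, seed=1,
        )
        with pytest.warns(UserWarning, match="no motif retained"):
            res = eg.build_prior_mlc(sim.signal, sim.rankings, sim.regions,
                                     sim.tss, alpha=0.0)
        assert res.network.n_edges == 0


class TestBuildPriorMethcor:
    def test_planted_anticorrelation_retained(self):
        sim = eg.simulate_epigenome(
            n_regions=800, n_motifs=12, active_motifs=3, effect=0.3,
            mode="methylation", n_samples=6, seed=9,
        )
        res = eg.build_prior_methcor(sim.signal, sim.rankings, sim.regions,
                                     sim.tss)
        active = set(sim.active_motifs)
        assert active <= set(res.retained_motifs)
        # planted effect lowers methylation at well-matched regions
        a = res.associations
        planted = a[a.motif_id.isin(active)].dropna(subset=["statistic"])
        assert (planted.statistic < 0).mean() > 0.9

    def test_low_coverage_regions_excluded(self):
        sim = eg.simulate_epigenome(
            n_regions=100, n_motifs=4, active_motifs=1, effect=0.3,
            n_samples=4, seed=3,
        )
        cov = sim.signal.coverage.copy()
        cov.iloc[0] = [True, True, False, False]  # covered in 2 of 4 samples
        signal = eg.RegionSignalMatrix(values=sim.signal.values,
                                       coverage=cov, kind="methylation")
        model = eg.PriorNetworkModel(
            sim.rankings, signal, sim.regions, sim.tss,
            method="methcor", min_covered_samples=3,
        )
        assert sim.regions.region_ids[0] not in model._usable_regions()

    def test_constant_signal_skipped_per_sample(self):
        sim = eg.simulate_epigenome(
            n_regions=50, n_motifs=3, active_motifs=0, effect=0.0,
            n_samples=3, seed=5,
        )
        vals = sim.signal.values.copy()
        vals["s1"] = 0.5  # constant in sample 1
        signal = eg.RegionSignalMatrix(values=vals, kind="methylation")
        res = eg.PriorNetworkModel(
            sim.rankings, signal, sim.regions, sim.tss, method="methcor",
        ).fit()
        s1 = res.associations[res.associations.sample_id == "s1"]
        assert s1["statistic"].isna().all()


class TestPriorInvariants:
    def test_region_order_permutation_invariance(self):
        sim = eg.simulate_epigenome(
            n_regions=300, n_motifs=8, active_motifs=2, effect=0.3,
            n_samples=5, seed=21,
        )
        res1 = eg.build_prior_methcor(sim.signal, sim.rankings, sim.regions,
                                      sim.tss)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sim.regions))
        regions2 = eg.RegionSet(sim.regions.df.iloc[perm])
        signal2 = eg.RegionSignalMatrix(
            values=sim.signal.values.iloc[perm],
            coverage=sim.signal.coverage.iloc[perm],
            kind="methylation",
        )
        ranks2 = eg.MotifRankingMatrix(
            sim.rankings.ranks.iloc[:, perm], dict(sim.rankings.motif_to_tf)
        )
        res2 = eg.build_prior_methcor(signal2, ranks2, regions2, sim.tss)
        assert res1.network.edges() == res2.network.edges()

    def test_support_regions_satisfy_promoter_rule(self):
        sim = eg.simulate_epigenome(
            n_regions=400, n_motifs=8, active_motifs=3, effect=0.4,
            n_samples=5, seed=31,
        )
        res = eg.build_prior_methcor(sim.signal, sim.rankings, sim.regions,
                                     sim.tss, max_dist=5000)
        rg = eg.assign_regions_to_genes(sim.regions, sim.tss, max_dist=5000)
        dist = {r.region_id: (r.gene_id, r.distance)
                for r in rg.df.itertuples()}
        assert res.network.n_edges > 0
        for (tf, target), regions in res.network.support.items():
            for r in regions:
                gene, d = dist[r]
                assert gene == target and d < 5000

    def test_prior_round_trip_tsv(self, tmp_path):
        net = eg.PriorNetwork(
            parents={"g1": frozenset({"TF1", "TF2"}), "g2": frozenset({"TF1"})},
            support={("TF1", "g1"): frozenset({"r1", "r2"})},
            provenance="methcor",
        )
        path = tmp_path / "prior.tsv"
        net.to_tsv(path)
        back = eg.PriorNetwork.from_tsv(path)
        assert back.parents == net.parents
        assert back.support[("TF1", "g1")] == net.support[("TF1", "g1")]
        assert back.provenance == "methcor"
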