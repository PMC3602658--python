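import numpy as np
import pandas as pd
import pytest

import localmotif as lm
from localmotif import global_stats as gs
from localmotif import synthdata as sd
from localmotif.motif_scan import Site, SiteCollection
from localmotif.regions import EnrichedRegion


def _coll(site_map, motif="m", width=6, category="strong"):
    per_seq = {
        g: [Site(int(p), "+", 0.0, 1.0, category) for p in sites]
        for g, sites in site_map.items()
    }
    return SiteCollection(motif, width, per_seq)


class TestORI:
    def test_hand_computed_toy_value(self):
        # S: 10 sequences, 5 upstream sites spread over 4 of them;
        # genomic: 1000 sequences, 100 sites in 90 of them
        s_map = {f"s{i}": [] for i in range(10)}
        for g, sites in zip(["s0", "s1", "s2", "s3"], [[-10, -20], [-30], [-40], [-50]]):
            s_map[g] = sites
        g_map = {f"g{i}": [] for i in range(1000)}
        for i in range(90):
            g_map[f"g{i}"] = [-100]
        for i in range(10):
            g_map[f"g{i}"].append(-200)
        res = gs.ori(_coll(s_map), _coll(g_map), list(s_map), list(g_map))
        assert res.density_s == pytest.approx(0.5)
        assert res.density_genomic == pytest.approx(0.1)
        assert res.proportion_s == pytest.approx(0.4)
        assert res.proportion_genomic == pytest.approx(0.09)
        assert res.ori == pytest.approx((0.5 / 0.1) * (0.4 / 0.09), abs=1e-9)

    def test_self_comparison_is_exactly_one(self, universe, common_sites):
        res = gs.ori(common_sites, common_sites, universe.gene_ids, universe.gene_ids)
        assert res.ori == 1.0

    def test_zero_sites_in_s_gives_zero(self):
        s_map = {"s0": [], "s1": []}
        g_map = {"g0": [-10], "g1": []}
        res = gs.ori(_coll(s_map), _coll(g_map), list(s_map), list(g_map))
        assert res.ori == 0.0

    def test_zero_genomic_density_is_an_error(self):
        s_map = {"s0": [-10]}
        g_map = {"g0": [], "g1": []}
        with pytest.raises(ValueError, match="genomic"):
            gs.ori(_coll(s_map), _coll(g_map), list(s_map), list(g_map))

    def test_counting_window_is_upstream_kb_half_open(self):
        # sites at 0 and -1001 are outside [-1000, 0); -1000 is inside
        s_map = {"s0": [0, -1001, -1000]}
        g_map = {"g0": [-500]}
        res = gs.ori(_coll(s_map), _coll(g_map), list(s_map), list(g_map))
        assert res.density_s == pytest.approx(1.0)

    def test_order_invariance(self, universe, common_sites):
        ids = universe.gene_ids
        res1 = gs.ori(common_sites, common_sites, ids[:50], ids)
        res2 = gs.ori(common_sites, common_sites, ids[:50][::-1], ids[::-1])
        assert res1.ori == pytest.approx(res2.ori)


class TestPORI:
    def test_observed_above_all_samples_gives_zero(self, universe, gc2, common_sites):
        # an input handpicked as the most site-rich promoters beats any sample
        counts = gs.upstream_counts(common_sites, universe.gene_ids)
        top = np.argsort(counts)[-30:]
        input_set = universe.subset_indices(top)
        sites_s = common_sites.subset(input_set.gene_ids)
        res = gs.ori(sites_s, common_sites, input_set.gene_ids, universe.gene_ids)
        p = gs.p_ori(res, universe, common_sites, gc2, input_set,
                     n_samples=200, seed=5)
        assert p == 0.0

    def test_reproducible_under_seed(self, universe, gc2, common_sites):
        input_set = universe.subset_indices(range(40))
        sites_s = common_sites.subset(input_set.gene_ids)
        res = gs.ori(sites_s, common_sites, input_set.gene_ids, universe.gene_ids)
        p1 = gs.p_ori(res, universe, common_sites, gc2, input_set, 300, seed=9)
        p2 = gs.p_ori(res, universe, common_sites, gc2, input_set, 300, seed=9)
        assert p1 == p2


class TestWeakSites:
    def test_overlapping_weak_sites_excluded_from_count(self):
        region = EnrichedRegion("m", -50, -40, 10)
        sites = SiteCollection(
            "m", 6,
            {
                "s0": [
                    Site(-45, "+", 0.0, 1.0, "weak", overlaps_strong=True),
                    Site(-44, "+", 0.0, 1.0, "weak", overlaps_strong=False),
                    Site(-100, "+", 0.0, 1.0, "weak", overlaps_strong=False),
                ]
            },
        )
        counts = gs._weak_region_counts(sites, ["s0"], -60, -30)
        assert counts.tolist() == [1]

    def test_depleted_observation_has_p_near_one(self, universe, gc2, sharp_sites):
        # region where the universe has plenty of weak sites but the input none
        region = EnrichedRegion("sharp8", -50, 50, 100)
        per_gene = gs._weak_region_counts(
            sharp_sites, universe.gene_ids, region.region_start, region.region_end
        )
        empty_idx = np.nonzero(per_gene == 0)[0][:30]
        input_set = universe.subset_indices(empty_idx)
        sites_s = sharp_sites.subset(input_set.gene_ids)
        res = gs.weak_site_enrichment(
            region, sites_s, universe, sharp_sites, gc2, input_set,
            n_samples=200, seed=11,
        )
        assert res.n_weak_obs == 0
        assert res.p_value > 0.9

    def test_implanted_weak_sites_are_enriched(self, universe, gc2, sharp_sites):
        # implanting the sharp motif yields sub-threshold (weak) copies too
        rng = np.random.default_rng(13)
        input_set = universe.subset_indices(rng.choice(2000, 60, replace=False))
        implanted, _ = sd.implant(
            input_set,
            sd.ImplantSpec(motif=sd.implant_motif(), center=-100,
                           positional_sd=10, insertion_rate=0.8),
            seed=14,
        )
        sites_s = lm.scan(implanted, sd.implant_motif())
        region = EnrichedRegion("sharp8", -120, -80, 20)
        res = gs.weak_site_enrichment(
            region, sites_s, universe, sharp_sites, gc2, implanted,
            n_samples=300, seed=15,
        )
        assert res.n_weak_obs > res.null_mean
        assert res.p_value < 0.01


class TestConservationZ:
    def _track_and_sites(self, universe, elevated_region=None):
        rng = np.random.default_rng(21)
        gene_ids = universe.gene_ids[:200]
        positions = np.arange(-150, 150)
        rows = []
        for g in gene_ids:
            base = rng.uniform(0.2, 0.4, size=positions.size)
            rows.append(
                pd.DataFrame({"gene_id": g, "position": positions, "score": base})
            )
        track = pd.concat(rows, ignore_index=True)
        return gene_ids, track

    def test_z_formula_and_degenerate_track(self, universe):
        gene_ids, frame = self._track_and_sites(universe)
        sites = _coll({g: [] for g in gene_ids})
        sites.per_sequence[gene_ids[0]] = [Site(-100, "+", 0.0, 1.0, "strong")] * 10
        region = EnrichedRegion("m", -110, -90, 10)
        track = gs.ScoreTrack(frame)
        res = gs.conservation_z(
            region, sites, track, universe.subset(gene_ids), n_samples=100, seed=3
        )
        assert res.z == pytest.approx(
            (res.mean_obs - res.null_mean) / res.null_sd
        )
        flat = frame.copy()
        flat["score"] = 0.5
        with pytest.raises(ValueError, match="degenerate"):
            gs.conservation_z(
                region, sites, gs.ScoreTrack(flat),
                universe.subset(gene_ids), n_samples=50, seed=3,
            )

    def test_too_few_sites_rejected(self, universe):
        gene_ids, frame = self._track_and_sites(universe)
        sites = _coll({g: [] for g in gene_ids})
        sites.per_sequence[gene_ids[0]] = [Site(-100, "+", 0.0, 1.0, "strong")]
        region = EnrichedRegion("m", -110, -90, 10)
        with pytest.raises(ValueError, match="need >= 10"):
            gs.conservation_z(
                region, sites, gs.ScoreTrack(frame),
                universe.subset(gene_ids), n_samples=10, seed=1,
            )

    def test_elevated_site_scores_give_high_z(self, universe):
        gene_ids, frame = self._track_and_sites(universe)
        # put 12 sites at -100 in distinct genes and raise the track there
        site_map = {g: [] for g in gene_ids}
        carriers = gene_ids[:12]
        for g in carriers:
            site_map[g] = [-100]
        sites = _coll(site_map)
        w = sites.width
        start = -100 - (w - 1) // 2
        covered = (frame["gene_id"].isin(carriers)) & (
            frame["position"].between(start, start + w - 1)
        )
        frame.loc[covered, "score"] = 0.95
        region = EnrichedRegion("m", -110, -90, 10)
        res = gs.conservation_z(
            region, sites, gs.ScoreTrack(frame),
            universe.subset(gene_ids), n_samples=200, seed=8,
        )
        assert res.z > 3

    def test_missing_track_value_is_reported(self, universe):
        gene_ids, frame = self._track_and_sites(universe)
        sites = _coll({gene_ids[0]: [-100] * 10})
        region = EnrichedRegion("m", -110, -90, 10)
        clipped = frame[frame["position"] > -99]
        with pytest.raises(KeyError, match="position"):
            gs.conservation_z(
                region, sites, gs.ScoreTrack(clipped),
                universe.subset(gene_ids), n_samples=10, seed=1,
            )
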