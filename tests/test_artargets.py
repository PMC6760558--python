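import numpy as np
import pandas as pd
import pytest

from etsar import AnnotationParams, annotate_targets, simulate_cohort
from etsar.simulate import SimulationConfig


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "source"])


def brute_force_annotation(genes, sites, params):
    """Direct per-gene loop over all sites, straight from the definitions."""
    out = {}
    for _, g in genes.iterrows():
        dists_by_source = {}
        for _, s in sites.iterrows():
            if s["chrom"] != g["chrom"]:
                continue
            if s["start"] <= g["tss"] < s["end"]:
                d = 0
            elif g["tss"] < s["start"]:
                d = s["start"] - g["tss"]
            else:
                d = g["tss"] - s["end"] + 1
            if params.mode == "downstream_only" and d > 0:
                if g["strand"] == "+" and not (s["start"] >= g["tss"]):
                    continue
                if g["strand"] == "-" and not (s["end"] <= g["tss"] + 1):
                    continue
            dists_by_source.setdefault(s["source"], []).append(d)
        qualifying = {src for src, ds in dists_by_source.items()
                      if min(ds) <= params.window_bp}
        all_d = [d for ds in dists_by_source.values() for d in ds]
        out[g["gene_id"]] = (
            len(qualifying) >= params.min_sources,
            len(qualifying),
            min(all_d) if all_d else None,
        )
    return out


class TestConstructedCases:
    def test_site_2kb_downstream_is_target(self):
        genes = _genes([("g", "chr1", 10_000, "+")])
        sites = _sites([("chr1", 12_000, 12_500, "a")])
        res = annotate_targets(genes, sites)
        assert bool(res.loc["g", "is_target"])
        assert res.loc["g", "min_distance_bp"] == 2_000

    def test_site_30kb_away_not_target_at_default_window(self):
        genes = _genes([("g", "chr1", 10_000, "+")])
        sites = _sites([("chr1", 40_000, 41_000, "a")])
        res = annotate_targets(genes, sites)
        assert not bool(res.loc["g", "is_target"])
        assert res.loc["g", "min_distance_bp"] == 30_000

    def test_minus_strand_downstream_geometry(self):
        """For a minus-strand gene a site at higher coordinates is 5' of
        the TSS: non-target in downstream_only mode, target in symmetric."""
        genes = _genes([("g", "chr1", 50_000, "-")])
        sites = _sites([("chr1", 60_000, 61_000, "a")])
        down = annotate_targets(genes, sites, AnnotationParams(mode="downstream_only"))
        sym = annotate_targets(genes, sites, AnnotationParams(mode="symmetric"))
        assert not bool(down.loc["g", "is_target"])
        assert bool(sym.loc["g", "is_target"])

    def test_gene_on_siteless_chromosome_is_plain_nontarget(self):
        genes = _genes([("g", "chrX", 1_000, "+")])
        sites = _sites([("chr1", 500, 600, "a")])
        res = annotate_targets(genes, sites)
        assert not bool(res.loc["g", "is_target"])
        assert np.isnan(res.loc["g", "min_distance_bp"])

    def test_malformed_strand_rejected(self):
        genes = _genes([("g", "chr1", 1_000, "x")])
        sites = _sites([("chr1", 500, 600, "a")])
        with pytest.raises(ValueError, match="strand"):
            annotate_targets(genes, sites)

    def test_min_sources_requires_distinct_datasets(self):
        genes = _genes([("g", "chr1", 10_000, "+")])
        two_same = _sites([("chr1", 11_000, 11_200, "a"), ("chr1", 12_000, 12_200, "a")])
        two_diff = _sites([("chr1", 11_000, 11_200, "a"), ("chr1", 12_000, 12_200, "b")])
        params = AnnotationParams(min_sources=2)
        assert not bool(annotate_targets(genes, two_same, params).loc["g", "is_target"])
        assert bool(annotate_targets(genes, two_diff, params).loc["g", "is_target"])


class TestProperties:
    @pytest.fixture
    def random_geometry(self):
        rng = np.random.default_rng(17)
        genes = _genes([
            (f"g{i}", rng.choice(["chr1", "chr2"]), int(rng.integers(0, 200_000)),
             rng.choice(["+", "-"]))
            for i in range(30)
        ])
        sites = _sites([
            (rng.choice(["chr1", "chr2"]),) + (lambda s: (s, s + int(rng.integers(100, 2_000))))(
                int(rng.integers(0, 200_000))
            ) + (rng.choice(["a", "b", "c"]),)
            for _ in range(40)
        ])
        return genes, sites

    @pytest.mark.parametrize("mode", ["symmetric", "downstream_only"])
    @pytest.mark.parametrize("min_sources", [1, 2])
    def test_matches_brute_force(self, random_geometry, mode, min_sources):
        genes, sites = random_geometry
        params = AnnotationParams(window_bp=20_000, mode=mode, min_sources=min_sources)
        res = annotate_targets(genes, sites, params)
        expected = brute_force_annotation(genes, sites, params)
        for gene_id, (is_t, n_src, min_d) in expected.items():
            assert bool(res.loc[gene_id, "is_target"]) == is_t, gene_id
            assert res.loc[gene_id, "n_supporting_sources"] == n_src, gene_id
            got = res.loc[gene_id, "min_distance_bp"]
            if min_d is None:
                assert np.isnan(got)
            elif params.mode == "symmetric":
                assert got == min_d, gene_id

    def test_window_monotonicity(self, random_geometry):
        genes, sites = random_geometry
        small = annotate_targets(genes, sites, AnnotationParams(window_bp=5_000))
        large = annotate_targets(genes, sites, AnnotationParams(window_bp=50_000))
        assert (large["is_target"] | ~small["is_target"]).all()

    def test_site_order_invariance(self, random_geometry):
        genes, sites = random_geometry
        shuffled = sites.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = annotate_targets(genes, sites)
        b = annotate_targets(genes, shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestGroundTruthRecovery:
    def test_exact_on_simulated_geometry(self, small_cohort):
        res = annotate_targets(small_cohort.gene_models, small_cohort.binding_sites)
        assert (res["is_target"] == small_cohort.truth["is_ar_target"]).all()

    def test_downstream_mode_also_exact_on_simulated_geometry(self):
        """The generator places sites 3' of the TSS, so both modes agree."""
        cfg = SimulationConfig(n_genes=150, n_per_category=4, n_tumor_ets_pos=5,
                               n_tumor_ets_neg=5, n_normal=2, seed=33)
        c = simulate_cohort(cfg)
        res = annotate_targets(c.gene_models, c.binding_sites,
                               AnnotationParams(mode="downstream_only"))
        assert (res["is_target"] == c.truth["is_ar_target"]).all()
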