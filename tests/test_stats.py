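import numpy as np
import pandas as pd
import pytest

from mirclip.coverage import GeneDepth, InsufficientDataError
from mirclip.seedscan import SeedSite
from mirclip.stats import (
    NO_SEED, SEED_3UTR, SEED_3UTR_AHC5, TARGETSCAN,
    TIER_BOUND, TIER_HIGH, TIER_NONE, TIER_SEED, UP, DOWN, NS,
    Config, SchemaError, call_targets, cdf_shift, classify_genes,
    depth_by_direction, enrichment_score, intersect_signature, load_de_table,
    mannwhitney, read_gene_list,
)
from mirclip.transcriptome import CDS, THREE_UTR

from oracles import ecdf_sup, enrichment_brute, mannwhitney_enumeration


def de_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "mean_rpm", "log2fc", "p", "padj"])


def de_tsv(rows):
    return de_frame(rows).to_csv(sep="\t", index=False)


def site(gene, region=THREE_UTR, t0=0):
    return SeedSite(gene_id=gene, transcript_id=f"t_{gene}", region=region,
                    t_start=t0, t_end=t0 + 8, site_type="EIGHTMER", family="f")


class TestLoadDeTable:
    def test_expression_filter_is_inclusive_at_threshold(self):
        rows = [("g_low", 4.9, 0.1, 0.5, 0.9), ("g_at", 5.0, 0.1, 0.5, 0.9),
                ("g_hi", 50.0, 0.1, 0.5, 0.9)]
        df = load_de_table(de_tsv(rows))
        assert list(df["gene_id"]) == ["g_at", "g_hi"]

    def test_empty_table(self):
        assert len(load_de_table(de_tsv([]))) == 0

    def test_duplicate_gene_rejected(self):
        rows = [("g1", 10, 0, 0.5, 0.9)] * 2
        with pytest.raises(SchemaError, match="duplicate"):
            load_de_table(de_tsv(rows))

    def test_missing_column_rejected(self):
        bad = "gene_id\tmean_rpm\tlog2fc\tp\ng\t10\t0\t0.5\n"
        with pytest.raises(SchemaError, match="padj"):
            load_de_table(bad)

    def test_p_outside_unit_interval_rejected(self):
        rows = [("g1", 10, 0, 1.5, 0.9)]
        with pytest.raises(SchemaError, match="p"):
            load_de_table(de_tsv(rows))


class TestClassify:
    def test_three_utr_site_with_depth_support(self):
        de = de_frame([("g1", 10, 0.4, 0.01, 0.05)])
        classes = classify_genes(de, [site("g1")], {"g1": GeneDepth(depth_3utr=7)})
        row = classes.iloc[0]
        assert row["gene_class"] == SEED_3UTR and row["ahc5"]

    def test_cds_only_site_is_background_for_3utr_analyses(self):
        de = de_frame([("g1", 10, 0.4, 0.01, 0.05)])
        classes = classify_genes(de, [site("g1", region=CDS)],
                                 {"g1": GeneDepth(depth_5cds=3)})
        row = classes.iloc[0]
        assert row["gene_class"] == NO_SEED and row["seed_5cds_only"]

    def test_no_sites_no_flags(self):
        de = de_frame([("g1", 10, 0.4, 0.01, 0.05)])
        row = classify_genes(de, [], {}).iloc[0]
        assert row["gene_class"] == NO_SEED
        assert not (row["ahc5"] or row["seed_5cds_only"] or row["targetscan"])

    def test_targetscan_flag_restricted_to_expressed(self):
        de = de_frame([("g1", 10, 0.4, 0.01, 0.05)])
        classes = classify_genes(de, [], {}, targetscan=["g1", "g_absent"])
        assert classes.iloc[0]["targetscan"]


class TestCdfShift:
    @staticmethod
    def _setup(class_fc, bg_fc):
        rows = ([(f"c{i}", 10, fc, 0.5, 0.9) for i, fc in enumerate(class_fc)]
                + [(f"b{i}", 10, fc, 0.5, 0.9) for i, fc in enumerate(bg_fc)])
        de = de_frame(rows)
        sites = [site(f"c{i}") for i in range(len(class_fc))]
        classes = classify_genes(de, sites, {})
        return de, classes

    def test_identical_distributions(self):
        vals = list(np.linspace(-1, 1, 20))
        de, classes = self._setup(vals, vals)
        r = cdf_shift(de, classes, [(SEED_3UTR, NO_SEED)])[(SEED_3UTR, NO_SEED)]
        assert r.ks_d == 0.0 and r.median_shift == 0.0

    def test_shifted_class_against_bruteforce_ecdf(self):
        rng = np.random.default_rng(10)
        bg = rng.normal(size=100)
        cls = bg + 0.5
        de, classes = self._setup(list(cls), list(bg))
        r = cdf_shift(de, classes, [(SEED_3UTR, NO_SEED)])[(SEED_3UTR, NO_SEED)]
        assert r.ks_d == pytest.approx(ecdf_sup(cls, bg), abs=1e-12)
        assert r.median_shift == pytest.approx(0.5)

    def test_ecdf_curves_are_proper_step_functions(self):
        rng = np.random.default_rng(11)
        de, classes = self._setup(list(rng.normal(size=30)),
                                  list(rng.normal(size=50)))
        r = cdf_shift(de, classes, [(SEED_3UTR, NO_SEED)])[(SEED_3UTR, NO_SEED)]
        for x, y in (r.ecdf_class, r.ecdf_background):
            assert (np.diff(x) >= 0).all() and (np.diff(y) > 0).all()
            assert y[-1] == 1.0

    def test_small_class_is_error(self):
        de, classes = self._setup([0.1], [0.0, 0.2, 0.3])
        with pytest.raises(InsufficientDataError):
            cdf_shift(de, classes, [(SEED_3UTR, NO_SEED)])

    def test_ks_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=40), rng.normal(0.3, 1, size=60)
        de1, c1 = self._setup(list(a), list(b))
        de2, c2 = self._setup(list(np.exp(a)), list(np.exp(b)))
        d1 = cdf_shift(de1, c1, [(SEED_3UTR, NO_SEED)])[(SEED_3UTR, NO_SEED)].ks_d
        d2 = cdf_shift(de2, c2, [(SEED_3UTR, NO_SEED)])[(SEED_3UTR, NO_SEED)].ks_d
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mannwhitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p == pytest.approx(0.1)

    def test_full_ties(self):
        u, p = mannwhitney([2, 2, 2], [2, 2, 2])
        assert u == 4.5 and p == pytest.approx(1.0)

    def test_u_statistics_sum_to_n1n2(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.integers(0, 6, size=rng.integers(1, 7)).tolist()
            y = rng.integers(0, 6, size=rng.integers(1, 7)).tolist()
            u1, _ = mannwhitney(x, y)
            u2, _ = mannwhitney(y, x)
            assert u1 + u2 == len(x) * len(y)

    def test_empty_group_is_error(self):
        with pytest.raises(InsufficientDataError):
            mannwhitney([], [1.0])

    def test_large_sample_normal_approximation_reasonable(self):
        rng = np.random.default_rng(14)
        x = rng.normal(1.0, 1, size=40)
        y = rng.normal(0.0, 1, size=40)
        _, p = mannwhitney(x, y)
        assert p < 0.01


class TestDepthByDirection:
    @staticmethod
    def _setup():
        rows, sites, depths = [], [], {}
        for i, (fc, d) in enumerate([(0.5, 9), (0.8, 7), (1.0, 8),
                                     (-0.5, 1), (-0.2, 2)]):
            g = f"g{i}"
            rows.append((g, 10, fc, 0.01, 0.05))
            sites.append(site(g))
            depths[g] = GeneDepth(depth_3utr=d)
        de = de_frame(rows)
        classes = classify_genes(de, sites, depths)
        return de, classes

    def test_up_genes_have_greater_depth(self):
        de, classes = self._setup()
        r = depth_by_direction(de, classes, THREE_UTR)
        assert (r.n_up, r.n_down) == (3, 2)
        assert r.median_up > r.median_down
        assert r.u == 6.0  # up-group wins every pairwise comparison

    def test_empty_direction_group_is_error(self):
        de, classes = self._setup()
        de = de.assign(log2fc=de["log2fc"].abs())  # nothing downregulated
        with pytest.raises(InsufficientDataError):
            depth_by_direction(de, classes, THREE_UTR)


class TestEnrichment:
    def test_single_hit_at_top_gives_es_one(self):
        ranked = [(f"g{i}", 10.0 - i) for i in range(10)]
        r = enrichment_score(ranked, {"g0"})
        assert r.es == pytest.approx(1.0)

    def test_matches_bruteforce_running_sum(self):
        ranked = [(f"g{i}", 10.0 - i) for i in range(10)]
        gene_set = {"g0", "g1", "g2"}
        r = enrichment_score(ranked, gene_set)
        hit = np.array([g in gene_set for g, _ in ranked])
        scores = np.array([s for _, s in ranked])
        es_ref, run_ref = enrichment_brute(scores, hit)
        assert r.es == pytest.approx(es_ref)
        assert np.allclose(r.running_curve, run_ref)

    def test_curve_starts_and_ends_at_zero(self):
        rng = np.random.default_rng(15)
        scores = np.sort(rng.normal(size=40))[::-1]
        ranked = [(f"g{i}", float(s)) for i, s in enumerate(scores)]
        r = enrichment_score(ranked, {f"g{i}" for i in range(0, 40, 7)})
        assert r.running_curve[0] == 0.0
        assert abs(r.running_curve[-1]) < 1e-9

    def test_negative_enrichment_for_bottom_heavy_set(self):
        ranked = [(f"g{i}", 10.0 - i) for i in range(10)]
        r = enrichment_score(ranked, {"g8", "g9"})
        assert r.es < 0

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enrichment_score([("g", 1.0), ("g", 0.5)], {"g"})

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersection"):
            enrichment_score([("a", 1.0), ("b", 0.5)], {"zzz"})

    def test_permutation_p_small_for_top_heavy_set(self):
        ranked = [(f"g{i}", 20.0 - i) for i in range(20)]
        r = enrichment_score(ranked, {"g0", "g1", "g2"}, n_perm=200, seed=0)
        assert r.perm_p is not None and r.perm_p < 0.1


class TestTargetCalls:
    @staticmethod
    def _calls(fc, p, depth, has_site=True):
        de = de_frame([("g1", 10, fc, p, p)])
        sites = [site("g1")] if has_site else []
        depths = {"g1": GeneDepth(depth_3utr=depth)} if has_site else {}
        classes = classify_genes(de, sites, depths)
        return call_targets(de, classes)[0]

    def test_no_seed_is_tier_none(self):
        c = self._calls(0.4, 0.01, 0, has_site=False)
        assert c.tier == TIER_NONE and c.direction == UP

    def test_full_evidence_is_high_confidence(self):
        c = self._calls(0.4, 0.01, 7)
        assert c.tier == TIER_HIGH and c.direction == UP

    def test_low_depth_stays_seed_only(self):
        c = self._calls(0.4, 0.01, 2)
        assert c.tier == TIER_SEED and c.direction == UP

    def test_bound_but_downregulated_not_high_confidence(self):
        c = self._calls(-0.4, 0.01, 7)
        assert c.tier == TIER_BOUND and c.direction == DOWN

    def test_not_significant_direction_ns(self):
        c = self._calls(0.4, 0.5, 7)
        assert c.tier == TIER_BOUND and c.direction == NS

    def test_tier_lattice_on_simulation(self, small_sim):
        _, result, _, _ = small_sim
        counts = result.call_counts()
        n_high = counts.get(TIER_HIGH, 0)
        n_bound = n_high + counts.get(TIER_BOUND, 0)
        n_seed = n_bound + counts.get(TIER_SEED, 0)
        assert n_high <= n_bound <= n_seed


class TestSignature:
    def test_counts_split_by_direction(self):
        rows = [("g1", 10, 0.5, 0.05, 0.2), ("g2", 10, 0.3, 0.08, 0.3),
                ("g3", 10, -0.4, 0.02, 0.1), ("g4", 10, 0.5, 0.5, 0.9),
                ("g5", 10, 0.5, 0.05, 0.2)]
        de = de_frame(rows)
        sites = [site(g) for g in ("g1", "g2", "g3", "g4")]  # g5 lacks a site
        classes = classify_genes(de, sites, {})
        r = intersect_signature(de, classes, ["g1", "g2", "g3", "g4", "g5"])
        assert (r.n_hit, r.n_up, r.n_down) == (3, 2, 1)
        assert list(r.table["gene_id"]) == ["g1", "g2", "g3"]

    def test_signature_genes_absent_from_de_count_zero(self):
        de = de_frame([("g1", 10, 0.5, 0.05, 0.2)])
        classes = classify_genes(de, [], {})
        r = intersect_signature(de, classes, ["x", "y"])
        assert (r.n_hit, r.n_up, r.n_down) == (0, 0, 0)

    def test_empty_signature_is_error(self):
        de = de_frame([("g1", 10, 0.5, 0.05, 0.2)])
        classes = classify_genes(de, [], {})
        with pytest.raises(ValueError, match="empty"):
            intersect_signature(de, classes, [])


def test_config_thresholds_must_be_positive():
    with pytest.raises(ValueError):
        Config(depth_min=0)


def test_read_gene_list_skips_blank_and_comment_lines():
    assert read_gene_list("g1\n\n# note\ng2\n") == ["g1", "g2"]
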