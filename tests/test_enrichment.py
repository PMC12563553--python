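import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regcompare.enrichment import (
    MotifModel,
    base_composition,
    bh_adjust,
    cluster_enrichment,
    fisher_exact_2x2,
    gc_fraction,
    gc_length_matched_background,
    gene_set_enrichment,
    holm_adjust,
    load_motifs_jaspar,
    log_odds_matrix,
    motif_enrichment,
    scan_sequence,
    set_intersections,
)
from regcompare.io_formats import ValidationError


def enumerate_fisher_p(a, b, c, d):
    """Two-sided p by exhaustive enumeration over tables with fixed margins."""
    r1, c1, N = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, N, c1, r1)
    total = 0.0
    for x in range(max(0, r1 + c1 - N), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, N, c1, r1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisher:
    def test_balanced_table_is_null(self):
        or_, ci, p = fisher_exact_2x2(10, 10, 10, 10)
        assert or_ == 1.0 and p == 1.0
        assert ci[0] < 1.0 < ci[1]

    def test_extreme_table_point_mass(self):
        # (5,0,0,5): two-sided p = 2 * 1/C(10,5) = 2/252
        _, _, p = fisher_exact_2x2(5, 0, 0, 5)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(enumerate_fisher_p(a, b, c, d), rel=1e-6)
            checked += 1

    def test_haldane_correction_on_zero_cell(self):
        or_, ci, _ = fisher_exact_2x2(5, 0, 0, 5)
        assert or_ == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))
        assert np.isfinite(ci[0]) and np.isfinite(ci[1])

    def test_woolf_ci_closed_form(self):
        import math

        or_, ci, _ = fisher_exact_2x2(20, 10, 5, 15)
        want_or = 20 * 15 / (10 * 5)
        se = math.sqrt(1 / 20 + 1 / 10 + 1 / 5 + 1 / 15)
        assert or_ == pytest.approx(want_or)
        assert ci[0] == pytest.approx(math.exp(math.log(want_or) - 1.96 * se))
        assert ci[1] == pytest.approx(math.exp(math.log(want_or) + 1.96 * se))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(0, 0, 3, 4)


class TestAdjustments:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_holm_hand_worked(self):
        got = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(got, [0.03, 0.06, 0.06])

    def test_bh_hand_worked(self):
        # p sorted: .01 .02 .03 .04 .05, m=5 -> raw m*p/i: .05 .05 .05 .05 .05
        got = bh_adjust([0.03, 0.01, 0.05, 0.02, 0.04])
        assert np.allclose(got, 0.05)
        got2 = bh_adjust([0.005, 0.04, 0.03])
        # sorted: .005 -> .015, .03 -> .045, .04 -> .04 -> monotone -> .045 stays? no:
        # step-up: i=3: .04; i=2: min(.045,.04)=.04; i=1: min(.015,.04)=.015
        assert np.allclose(got2, [0.015, 0.04, 0.04])

    def test_adjusted_values_bounded_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        for adj in (holm_adjust(p), bh_adjust(p)):
            assert (adj <= 1.0 + 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.5])


class TestClusterEnrichment:
    def test_identical_set_and_cluster_extreme(self):
        universe = {f"g{i}" for i in range(100)}
        cluster = {f"g{i}" for i in range(20)}
        res = cluster_enrichment(cluster, {"c1": cluster}, universe)
        (r,) = res
        assert r.a == 20 and r.b == 0 and r.c == 0
        assert r.p < 1e-15
        assert np.isfinite(r.odds_ratio)  # Haldane-corrected, not inf

    def test_planted_overrepresentation_recovered(self):
        # membership odds planted at OR = 2: p_in = 1/3, p_out = 1/5
        universe = [f"g{i}" for i in range(2000)]
        cluster = sorted(universe[:400])
        rest = sorted(set(universe) - set(cluster))
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            gene_set = {g for g in cluster if rng.random() < 1 / 3}
            gene_set |= {g for g in rest if rng.random() < 1 / 5}
            (r,) = cluster_enrichment(gene_set, {"c": set(cluster)}, set(universe))
            if 1.6 <= r.odds_ratio <= 2.5:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_stray_cluster_gene_rejected(self):
        with pytest.raises(ValidationError):
            cluster_enrichment({"a"}, {"c": {"zzz"}}, {"a", "b"})

    def test_holm_applied_across_clusters(self):
        universe = {f"g{i}" for i in range(60)}
        clusters = {f"c{j}": {f"g{i}" for i in range(j * 20, (j + 1) * 20)}
                    for j in range(3)}
        gene_set = {f"g{i}" for i in range(15)}
        res = cluster_enrichment(gene_set, clusters, universe)
        ps = [r.p for r in res]
        assert np.allclose([r.p_adj for r in res], holm_adjust(ps))


class TestGeneSetEnrichment:
    def test_query_equals_universe_is_null(self):
        universe = {f"g{i}" for i in range(50)}
        ann = {"s1": {f"g{i}" for i in range(10)}}
        df = gene_set_enrichment(universe, ann, universe, fdr=0.05)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_closed_form_hypergeometric_tail(self):
        universe = {f"g{i}" for i in range(1000)}
        members = {f"g{i}" for i in range(50)}
        query = members | {f"g{i}" for i in range(900, 950)}
        df = gene_set_enrichment(query, {"s": members}, universe)
        want = stats.hypergeom.sf(49, 1000, 50, 100)
        assert df.loc[0, "p"] == pytest.approx(float(want), rel=1e-9)
        assert bool(df.loc[0, "significant"])

    def test_empty_set_skipped(self):
        universe = {"a", "b"}
        df = gene_set_enrichment({"a"}, {"empty": set()}, universe)
        assert len(df) == 0


class TestSetIntersections:
    def test_disjoint_and_identical(self):
        df = set_intersections({"A": {1, 2}, "B": {3}})
        assert set(zip(df["sets"], df["size"])) == {("A", 2), ("B", 1)}
        df2 = set_intersections({"A": {1, 2}, "B": {1, 2}})
        assert set(zip(df2["sets"], df2["size"])) == {("A&B", 2)}

    def test_matches_brute_force_signature_tally(self):
        rng = np.random.default_rng(3)
        sets = {f"S{i}": set(rng.choice(500, size=rng.integers(20, 120),
                                        replace=False).tolist())
                for i in range(7)}
        df = set_intersections(sets)
        union = set().union(*sets.values())
        assert df["size"].sum() == len(union)
        tally = {}
        for el in union:
            sig = "&".join(n for n in sorted(sets) if el in sets[n])
            tally[sig] = tally.get(sig, 0) + 1
        assert dict(zip(df["sets"], df["size"])) == tally


PWM_TGCA = MotifModel(
    "TGCA",
    np.array([
        [0.0, 0.0, 0.0, 1.0],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [1.0, 0.0, 0.0, 0.0],
    ]),
)


class TestMotifs:
    def test_hand_computed_log_odds_window(self):
        bg = np.array([0.25, 0.25, 0.25, 0.25])
        lom = log_odds_matrix(PWM_TGCA, bg)
        # a perfect match scores 4 * log2(1/0.25) = 8 bits
        assert lom.max(axis=0).sum() == pytest.approx(8.0)
        assert scan_sequence("AATGCAAA", PWM_TGCA, bg)       # forward hit
        assert scan_sequence("AATGCATT", PWM_TGCA, bg)
        assert scan_sequence("TTTGCATT", PWM_TGCA, bg)       # revcomp TGCA = TGCA
        assert not scan_sequence("AAAAAAAA", PWM_TGCA, bg)

    def test_planted_motif_strongly_enriched(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        def rand_seq(n):
            return "".join(rng.choice(bases, size=n))
        fg = [rand_seq(20) + "TGCA" + rand_seq(20) for _ in range(40)]
        bg = ["".join(c for c in rand_seq(44) if True).replace("TGCA", "AAAA")
              for _ in range(40)]
        df = motif_enrichment(fg, bg, [PWM_TGCA], fdr=0.01)
        assert df.loc[0, "fg_hits"] == 40
        assert bool(df.loc[0, "significant"])

    def test_matched_background_is_not_enriched(self):
        fg = gc_length_matched_background(["ACGT" * 30] * 30, seed=1)
        bg = gc_length_matched_background(["ACGT" * 30] * 30, seed=2)
        df = motif_enrichment(fg, bg, [PWM_TGCA], fdr=0.01)
        assert not bool(df.loc[0, "significant"])

    def test_background_sampler_matches_gc_and_length(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        fg = ["".join(rng.choice(bases, size=int(rng.integers(50, 150)),
                                 p=[0.2, 0.3, 0.3, 0.2])) for _ in range(1000)]
        bg = gc_length_matched_background(fg, seed=9)
        assert [len(s) for s in bg] == [len(s) for s in fg]
        per_seq = [abs(gc_fraction(a) - gc_fraction(b)) for a, b in zip(fg, bg)]
        assert max(per_seq) <= 0.02 + 1e-9
        mean_gap = abs(np.mean([gc_fraction(s) for s in fg])
                       - np.mean([gc_fraction(s) for s in bg]))
        assert mean_gap <= 0.005

    def test_jaspar_round_trip(self, tmp_path):
        f = tmp_path / "m.jaspar"
        f.write_text(
            ">MA0001.1 toy\n"
            "A [ 0 10  0  0 ]\n"
            "C [ 0  0 10  0 ]\n"
            "G [10  0  0  0 ]\n"
            "T [ 0  0  0 10 ]\n"
        )
        (m,) = load_motifs_jaspar(f)
        assert m.length == 4
        assert np.allclose(m.pwm.sum(axis=0), 1.0)
        assert m.pwm[2, 0] > 0.9  # G dominates the first column
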