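import numpy as np
import pytest

from regcompare.classify import RegulatoryElement, annotate_nearest_gene
from regcompare.io_formats import (
    ChainAlignment,
    ChainBlock,
    GeneModel,
    GenomicInterval,
)
from regcompare.liftover import (
    conserved_activity,
    invert_chain,
    map_interval,
    reciprocal_filter,
)


def chain(t_name, t_size, t_start, blocks, q_name, q_size, q_start,
          q_strand="+", score=1000, chain_id=1):
    size = sum(b[0] for b in blocks)
    dt = sum(b[1] for b in blocks)
    dq = sum(b[2] for b in blocks)
    c = ChainAlignment(
        score, t_name, t_size, "+", t_start, t_start + size + dt,
        q_name, q_size, q_strand, q_start, q_start + size + dq, chain_id,
        tuple(ChainBlock(*b) for b in blocks),
    )
    c.validate()
    return c


IDENTITY = chain("tA", 1000, 0, [(1000, 0, 0)], "qA", 1000, 0)

# a 3-chromosome toy: identity, indels, and a strand flip
FIXTURE_CHAINS = [
    chain("t1", 1000, 0, [(1000, 0, 0)], "q1", 1000, 0, chain_id=1),
    chain("t2", 1000, 50, [(200, 30, 0), (300, 0, 40), (150, 0, 0)],
          "q2", 1200, 100, chain_id=2),
    chain("t3", 800, 100, [(250, 20, 10), (200, 0, 0)],
          "q3", 900, 150, q_strand="-", chain_id=3),
]


def brute_force_project(iv, chains, min_match):
    """Base-by-base projector, independent of the block-walking code."""
    covering = [c for c in chains
                if c.t_name == iv.chrom and c.t_start < iv.end and c.t_end > iv.start]
    if not covering:
        return ("unmapped", 0.0, None)
    best = max(covering, key=lambda c: (c.score, -c.chain_id))
    positions = []
    for pos in range(iv.start, iv.end):
        t = best.t_start
        q = best.q_start
        hit = None
        for b in best.blocks:
            if t <= pos < t + b.size:
                hit = q + (pos - t)
                break
            t += b.size + b.dt
            q += b.size + b.dq
        if hit is not None:
            fwd = hit if best.q_strand == "+" else best.q_size - 1 - hit
            positions.append(fwd)
    frac = len(positions) / iv.length
    if not positions or frac < min_match:
        return ("unmapped", frac, None)
    return ("mapped", frac,
            (best.q_name, min(positions), max(positions) + 1))


class TestMapInterval:
    def test_identity_chain_is_identity(self):
        m = map_interval(GenomicInterval("tA", 123, 456), [IDENTITY])
        assert m.status == "mapped" and m.mapped_fraction == 1.0
        assert (m.interval.start, m.interval.end) == (123, 456)

    def test_gap_inside_interval_fails_min_match(self):
        # dt=50 gap covering half of [100,200): only 50/100 bases aligned
        c = chain("tA", 1000, 0, [(150, 50, 0), (300, 0, 0)], "qA", 1000, 0)
        m = map_interval(GenomicInterval("tA", 100, 200), [c], min_match=0.95)
        assert m.status == "unmapped"
        assert m.mapped_fraction == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_base_by_base_projector(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            chrom = rng.choice(["t1", "t2", "t3"])
            size = {"t1": 1000, "t2": 1000, "t3": 800}[chrom]
            start = int(rng.integers(0, size - 30))
            end = start + int(rng.integers(10, min(300, size - start)))
            iv = GenomicInterval(chrom, start, end)
            for mm in (0.5, 0.95, 1.0):
                want = brute_force_project(iv, FIXTURE_CHAINS, mm)
                got = map_interval(iv, FIXTURE_CHAINS, mm)
                assert got.status == want[0]
                assert got.mapped_fraction == pytest.approx(want[1])
                if want[0] == "mapped":
                    assert (got.interval.chrom, got.interval.start,
                            got.interval.end) == want[2]

    def test_round_trip_through_inverse_chains_is_identity(self, small_genome):
        _, _, cab, cba, truth = small_genome
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(50):
            c = cab[int(rng.integers(len(cab)))]
            # pick an interval fully inside an aligned block
            t = c.t_start
            for b in c.blocks:
                if b.size > 40:
                    start = t + int(rng.integers(0, b.size - 30))
                    end = start + int(rng.integers(10, min(200, t + b.size - start)))
                    iv = GenomicInterval(c.t_name, start, end)
                    fwd = map_interval(iv, cab, 1.0)
                    assert fwd.status == "mapped"
                    back = map_interval(fwd.interval, cba, 1.0)
                    assert back.status == "mapped"
                    assert (back.interval.chrom, back.interval.start,
                            back.interval.end) == (iv.chrom, iv.start, iv.end)
                    checked += 1
                    break
                t += b.size + b.dt
        assert checked >= 30

    def test_lower_min_match_never_unmaps(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            start = int(rng.integers(0, 900))
            iv = GenomicInterval("t2", start, start + int(rng.integers(10, 100)))
            mapped = [map_interval(iv, FIXTURE_CHAINS, mm).status == "mapped"
                      for mm in (1.0, 0.95, 0.5, 0.05)]
            # once mapped at a strict cutoff, stays mapped at looser ones
            assert mapped == sorted(mapped)

    def test_best_scoring_chain_wins(self):
        lo = chain("tA", 1000, 0, [(1000, 0, 0)], "qLO", 1000, 0, score=10, chain_id=1)
        hi = chain("tA", 1000, 0, [(1000, 0, 0)], "qHI", 1000, 0, score=99, chain_id=2)
        m = map_interval(GenomicInterval("tA", 10, 20), [lo, hi])
        assert m.interval.chrom == "qHI"


def make_element(name, chrom, start, end, gene, cls="enhancer"):
    marks = frozenset({"H3K27ac"}) if cls == "enhancer" else frozenset({"H3K4me3"})
    return RegulatoryElement(GenomicInterval(chrom, start, end), cls, marks,
                             1.0, name, gene, 100)


class TestReciprocalFilter:
    genes = [GeneModel("g1", "tA", "+", 500, 100)]

    def test_identity_chains_keep_everything(self):
        inv = invert_chain(IDENTITY)
        elements = [make_element(f"e{i}", "tA", 100 * i + 10, 100 * i + 60, "g1")
                    for i in range(5)]
        elements = annotate_nearest_gene(elements, self.genes)
        kept, report = reciprocal_filter(elements, [IDENTITY], [inv], self.genes)
        assert len(kept) == 5
        assert (report["status"] == "alignable").all()

    def test_deleted_locus_is_dropped(self):
        # chain covers only [0,100) of tA: element at 300 has no aligned bases
        c = chain("tA", 1000, 0, [(100, 0, 0)], "qA", 1000, 0)
        element = annotate_nearest_gene(
            [make_element("e", "tA", 300, 350, "g1")], self.genes
        )
        kept, report = reciprocal_filter(element, [c], [invert_chain(c)], self.genes)
        assert kept == [] and report.loc[0, "status"] == "unmapped"

    def test_rearrangement_changing_nearest_gene_drops_element(self):
        # A->B maps [0,500); B->A maps back displaced to land near g2
        ab = chain("tA", 2000, 0, [(500, 0, 0)], "qA", 2000, 0)
        ba = chain("qA", 2000, 0, [(500, 0, 0)], "tA", 2000, 1200)
        genes = [GeneModel("g1", "tA", "+", 150, 100),
                 GeneModel("g2", "tA", "+", 1300, 100)]
        element = annotate_nearest_gene(
            [make_element("e", "tA", 100, 160, None)], genes
        )
        assert element[0].nearest_gene == "g1"
        kept, report = reciprocal_filter(element, [ab], [ba], genes)
        assert kept == []
        assert report.loc[0, "status"] == "nearest_gene_changed"
        assert report.loc[0, "roundtrip_gene"] == "g2"


class TestConservedActivity:
    def test_partition_and_calls(self):
        elements = [
            make_element("cons", "tA", 100, 200, "g1"),
            make_element("desert", "tA", 300, 400, "g1"),
            make_element("lost", "tA", 600, 700, "g1"),
        ]
        from regcompare.liftover import MappedElement

        mapped = {
            "cons": MappedElement("cons", "mapped", 1.0, GenomicInterval("qA", 100, 200)),
            "desert": MappedElement("desert", "mapped", 1.0, GenomicInterval("qA", 300, 400)),
        }
        b_elements = {"s1": [make_element("b1", "qA", 150, 250, "h1")],
                      "s2": [make_element("b2", "qA", 5000, 5100, "h2")]}
        table = conserved_activity(elements, mapped, b_elements).set_index("element")
        assert table.loc["cons", "label"] == "conserved"
        assert bool(table.loc["cons", "s1"]) and not bool(table.loc["cons", "s2"])
        assert table.loc["desert", "label"] == "speciesA_specific"
        assert table.loc["lost", "label"] == "unalignable"
        # every element labeled exactly once
        assert len(table) == 3

    def test_cross_class_overlap_is_not_conserved(self):
        from regcompare.liftover import MappedElement

        enh = make_element("e", "tA", 100, 200, "g1", cls="enhancer")
        mapped = {"e": MappedElement("e", "mapped", 1.0, GenomicInterval("qA", 100, 200))}
        b_prom = {"s1": [make_element("p", "qA", 100, 200, "h", cls="promoter")]}
        table = conserved_activity([enh], mapped, b_prom)
        assert table.loc[0, "label"] == "speciesA_specific"

    def test_planted_truth_recovered_without_jitter(self, small_genome):
        from regcompare.pipeline import Thresholds, classify_species, crossmap, evaluate_recovery
        from regcompare.synthetic import make_peak_replicates

        ga, gb, cab, cba, truth = small_genome
        peaks, emitted = make_peak_replicates(truth, jitter_sd=0.0, dropout=0.0, seed=0)
        th = Thresholds()
        eA, _ = classify_species(peaks["A"], ga, th)
        eB, _ = classify_species(peaks["B"], gb, th)
        activity = crossmap(eA, cab, cba, ga, {"B": eB}, th, truth.chrom_sizes_a)
        res = evaluate_recovery(truth, emitted, eA, activity)
        assert res["class_accuracy"] == 1.0
        assert res["conservation_accuracy"] == 1.0
        assert res["class_total"] == sum(
            1 for e in truth.elements if e.conservation != "speciesB_specific"
        )
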