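"""Synthetic two-genome fixtures with planted ground truth.

The generator emulates every input the pipeline consumes so that each stage
is testable without external data:

* a pair of toy genomes built from gene-sized segments, a known one-to-one
  orthology map on conserved segments, and mutually inverse UCSC chain files
  whose aligned blocks are exactly the conserved segments;
* regulatory elements planted near genes with a true class (promoters emit
  co-located H3K4me3+H3K27ac peaks, enhancers emit H3K27ac only) and a true
  conservation label (conserved elements have an active partner interval in
  the other genome; species-specific elements are alignable but active in
  one genome only);
* replicate narrowPeak sets with Normal endpoint jitter, per-peak dropout
  and log-normal fold enrichments;
* negative-binomial count matrices with planted temporal cluster profiles,
  flat (non-dynamic) genes, and species-specific high-expression genes.

A single integer seed drives one named substream per output so components
are independently reproducible; identical seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ChainAlignment,
    ChainBlock,
    GeneModel,
    GenomicInterval,
    Peak,
    ValidationError,
    write_chain,
    write_gene_models,
    write_narrowpeak,
)

_STREAMS = {"genome": 0, "elements": 1, "peaks_A": 2, "peaks_B": 3,
            "expr_A": 4, "expr_B": 5}

MARKS = ("H3K4me3", "H3K27ac")

# relative temporal profiles for the five planted clusters (interpolated to
# the requested number of stages); all exceed the 4x change-vs-baseline the
# dynamic-gene filter requires
_CLUSTER_PROFILES = np.array(
    [
        [1, 1, 1, 2, 8, 16],   # late ramp-up
        [16, 8, 2, 1, 1, 1],   # ramp-down
        [1, 1, 1, 1, 2, 12],   # last-stage peak
        [1, 2, 12, 12, 2, 1],  # mid peak
        [1, 8, 2, 1, 1, 1],    # early spike
    ],
    dtype=float,
)
N_CLUSTERS = _CLUSTER_PROFILES.shape[0]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass(frozen=True)
class TrueElement:
    name: str
    interval: GenomicInterval          # species-A coordinates
    true_class: str                    # enhancer | promoter
    conservation: str                  # conserved | speciesA_specific | speciesB_specific
    partner: GenomicInterval | None    # species-B coordinates when alignable
    gene_a: str                        # planted nearest gene in A


@dataclass
class SyntheticTruth:
    elements: list
    orthology_map: dict                # gene_id A -> gene_id B
    gene_truth: pd.DataFrame           # gene_id_a, gene_id_b, cluster, species_specific
    genes_a: list = field(default_factory=list)
    genes_b: list = field(default_factory=list)
    chains_ab: list = field(default_factory=list)
    chains_ba: list = field(default_factory=list)
    chrom_sizes_a: dict = field(default_factory=dict)
    chrom_sizes_b: dict = field(default_factory=dict)

    def elements_by_name(self) -> dict:
        return {e.name: e for e in self.elements}


def make_genome_pair(
    seed: int,
    n_chrom: int = 3,
    chrom_len: int = 300_000,
    n_genes: int = 30,
    conserved_frac: float = 0.8,
    n_elements: int = 60,
    element_conserved_frac: float = 0.3,
    b_specific_frac: float = 0.0,
    enhancer_frac: float = 0.6,
    flat_gene_frac: float = 0.1,
) -> tuple[list, list, list, list, SyntheticTruth]:
    """Build a toy genome pair with a known orthology map and chains.

    Each gene lives in its own segment; a segment is conserved with
    probability ``conserved_frac``, in which case it is carried unchanged
    into genome B (one aligned chain block, one-to-one ortholog). Adjacent
    conserved segments merge into a single chain block, so
    ``conserved_frac=1`` yields one identity block per chromosome and
    liftover is the identity. Non-conserved segments get independent lengths
    in B and fall into chain gaps.

    Elements are planted near their segment's TSS: conserved and
    species-specific elements go to conserved (alignable) segments;
    ``element_conserved_frac`` of them are conserved, ``b_specific_frac``
    active only in B, the rest active only in A.

    Returns (genes_A, genes_B, chains_A->B, chains_B->A, truth).
    """
    if not (0 <= conserved_frac <= 1):
        raise ValidationError("conserved_frac must be in [0, 1]")
    rng = _rng(seed, "genome")
    genes_per_chrom = [n_genes // n_chrom + (1 if c < n_genes % n_chrom else 0)
                       for c in range(n_chrom)]
    if min(genes_per_chrom) < 1:
        raise ValidationError("need at least one gene per chromosome")

    genes_a: list[GeneModel] = []
    genes_b: list[GeneModel] = []
    orthology: dict[str, str] = {}
    chains_ab: list[ChainAlignment] = []
    chrom_sizes_a: dict[str, int] = {}
    chrom_sizes_b: dict[str, int] = {}
    segments = []  # (chrom_a, a_start, a_end, b_start or None, conserved, gene_a_id)
    gid = 0
    for c in range(n_chrom):
        chrom_a = f"chrA{c + 1}"
        chrom_b = f"chrB{c + 1}"
        n_seg = genes_per_chrom[c]
        seg_len = chrom_len // n_seg
        if seg_len < 12_000:
            raise ValidationError(
                f"chrom_len {chrom_len} too small for {n_seg} genes "
                "(need >= 12 kb per gene segment)"
            )
        conserved = rng.random(n_seg) < conserved_frac
        b_lens = [
            seg_len if conserved[i] else int(rng.integers(int(0.8 * seg_len), int(1.2 * seg_len)))
            for i in range(n_seg)
        ]
        a_pos = 0
        b_pos = 0
        blocks: list[tuple[int, int, int, int]] = []  # (a_start, a_end, b_start, b_end)
        for i in range(n_seg):
            a_start, a_end = a_pos, a_pos + seg_len
            b_start, b_end = b_pos, b_pos + b_lens[i]
            tss_off = int(rng.integers(int(0.40 * seg_len), int(0.60 * seg_len)))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(1_000, 5_000))
            ga = f"geneA_{gid:05d}"
            gb = f"geneB_{gid:05d}"
            genes_a.append(GeneModel(ga, chrom_a, strand, a_start + tss_off, length,
                                     ortholog_id=gb if conserved[i] else None))
            genes_b.append(GeneModel(gb, chrom_b, strand, b_start + tss_off, length,
                                     ortholog_id=ga if conserved[i] else None))
            if conserved[i]:
                orthology[ga] = gb
                if blocks and blocks[-1][1] == a_start and blocks[-1][3] == b_start:
                    prev = blocks.pop()
                    blocks.append((prev[0], a_end, prev[2], b_end))
                else:
                    blocks.append((a_start, a_end, b_start, b_end))
            segments.append((chrom_a, a_start, a_end, b_start if conserved[i] else None,
                             bool(conserved[i]), ga, chrom_b))
            a_pos = a_end
            b_pos = b_end
            gid += 1
        chrom_sizes_a[chrom_a] = a_pos
        chrom_sizes_b[chrom_b] = b_pos
        if blocks:
            t_start, q_start = blocks[0][0], blocks[0][2]
            t_end, q_end = blocks[-1][1], blocks[-1][3]
            chain_blocks = []
            for i, (asr, aen, bsr, ben) in enumerate(blocks):
                size = aen - asr
                if i + 1 < len(blocks):
                    dt = blocks[i + 1][0] - aen
                    dq = blocks[i + 1][2] - ben
                else:
                    dt = dq = 0
                chain_blocks.append(ChainBlock(size, dt, dq))
            chain = ChainAlignment(
                score=1_000_000, t_name=chrom_a, t_size=a_pos, t_strand="+",
                t_start=t_start, t_end=t_end, q_name=chrom_b, q_size=b_pos,
                q_strand="+", q_start=q_start, q_end=q_end,
                chain_id=c + 1, blocks=tuple(chain_blocks),
            )
            chain.validate()
            chains_ab.append(chain)

    from .liftover import invert_chain

    chains_ba = [invert_chain(ch) for ch in chains_ab]

    # ---- plant elements ----
    erng = _rng(seed, "elements")
    alignable_segments = [s for s in segments if s[4]]
    placement_pool = alignable_segments if alignable_segments else segments
    elements: list[TrueElement] = []
    # offset slots relative to the TSS; promoters use near slots (stay within
    # the 3 kb high-confidence band), enhancers use distal slots
    promoter_slots = [0, 1100, -1100]
    enhancer_slots = [2600, -2600, 3900, -3900, 5200, -5200]
    slot_use: dict[int, dict[str, int]] = {}
    max_per_seg = len(promoter_slots) + len(enhancer_slots)
    if n_elements > max_per_seg * len(placement_pool):
        raise ValidationError(
            f"cannot place {n_elements} elements on {len(placement_pool)} "
            f"alignable segments (max {max_per_seg} per segment)"
        )
    order = erng.permutation(len(placement_pool))
    seg_cycle = [placement_pool[i] for i in order]
    p_cons = element_conserved_frac if alignable_segments else 0.0
    p_b = b_specific_frac if alignable_segments else 0.0
    k = 0
    for e_idx in range(n_elements):
        is_enh = erng.random() < enhancer_frac
        u = erng.random()
        conservation = ("conserved" if u < p_cons
                        else "speciesB_specific" if u < p_cons + p_b
                        else "speciesA_specific")
        placed = False
        for _try in range(len(seg_cycle)):
            seg = seg_cycle[k % len(seg_cycle)]
            k += 1
            seg_id = id(seg)
            use = slot_use.setdefault(seg_id, {"promoter": 0, "enhancer": 0})
            slots = enhancer_slots if is_enh else promoter_slots
            kind = "enhancer" if is_enh else "promoter"
            if use[kind] >= len(slots):
                continue
            off = slots[use[kind]]
            use[kind] += 1
            chrom_a, a_start, a_end, b_start, seg_cons, ga, chrom_b = seg
            tss = next(g.tss for g in genes_a if g.gene_id == ga)
            half = 250 if is_enh else 300
            center = tss + off
            lo, hi = center - half, center + half
            if lo < a_start + 10 or hi > a_end - 10:
                continue  # slot does not fit this segment; try the next one
            iv = GenomicInterval(chrom_a, lo, hi)
            partner = None
            cons = conservation if seg_cons else "speciesA_specific"
            if seg_cons:
                shift = b_start - a_start
                partner = GenomicInterval(chrom_b, lo + shift, hi + shift)
            elements.append(
                TrueElement(
                    name=f"elem_{e_idx:05d}",
                    interval=iv,
                    true_class=kind,
                    conservation=cons,
                    partner=partner,
                    gene_a=ga,
                )
            )
            placed = True
            break
        if not placed:
            raise ValidationError("element placement failed after bounded retries")

    # ---- gene truth: temporal cluster + species-specific flags ----
    grng = np.random.default_rng([seed, _STREAMS["elements"], 7])
    rows = []
    for g in genes_a:
        flat = grng.random() < flat_gene_frac
        cluster = -1 if flat else int(grng.integers(0, N_CLUSTERS))
        # species-specific high expression only makes sense with an ortholog
        spec = bool(g.ortholog_id) and grng.random() < 0.05
        rows.append({"gene_id_a": g.gene_id, "gene_id_b": g.ortholog_id or "",
                     "cluster": cluster, "species_specific": spec})
    gene_truth = pd.DataFrame(rows)

    truth = SyntheticTruth(
        elements=elements, orthology_map=orthology, gene_truth=gene_truth,
        genes_a=genes_a, genes_b=genes_b, chains_ab=chains_ab, chains_ba=chains_ba,
        chrom_sizes_a=chrom_sizes_a, chrom_sizes_b=chrom_sizes_b,
    )
    return genes_a, genes_b, chains_ab, chains_ba, truth


def make_peak_replicates(
    truth: SyntheticTruth,
    jitter_sd: float = 5.0,
    dropout: float = 0.1,
    seed: int = 0,
    n_reps: int = 2,
    fold_mu: float = 1.6,
    fold_sigma: float = 0.5,
) -> tuple[dict, pd.DataFrame]:
    """Replicate narrowPeak sets per species and mark.

    Each active element emits, per replicate, a peak per mark (promoters:
    both marks co-located; enhancers: H3K27ac only) with endpoints jittered
    ~Normal(0, jitter_sd) and dropped independently with probability
    ``dropout``. Fold enrichments are log-normal(mu=fold_mu, sigma=fold_sigma).

    Returns (peaks, emitted): ``peaks[species][mark]`` is a list of
    ``n_reps`` peak lists; ``emitted`` records one row per surviving peak
    (element, species, mark, rep) so recovery can be evaluated conditionally
    on the evidence that survived dropout.
    """
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be >= 0")
    if not (0 <= dropout < 1):
        raise ValidationError("dropout must be in [0, 1)")
    out: dict = {
        "A": {m: [[] for _ in range(n_reps)] for m in MARKS},
        "B": {m: [[] for _ in range(n_reps)] for m in MARKS},
    }
    emitted_rows = []
    for species in ("A", "B"):
        rng = _rng(seed, f"peaks_{species}")
        sizes = truth.chrom_sizes_a if species == "A" else truth.chrom_sizes_b
        for e in truth.elements:
            if species == "A":
                if e.conservation == "speciesB_specific":
                    continue
                iv = e.interval
            else:
                if e.conservation == "speciesA_specific" or e.partner is None:
                    continue
                iv = e.partner
            marks = MARKS if e.true_class == "promoter" else ("H3K27ac",)
            for mark in marks:
                for r in range(n_reps):
                    drop = rng.random() < dropout
                    j1 = int(round(rng.normal(0, jitter_sd))) if jitter_sd else 0
                    j2 = int(round(rng.normal(0, jitter_sd))) if jitter_sd else 0
                    fold = float(rng.lognormal(fold_mu, fold_sigma))
                    if drop:
                        continue
                    start = max(0, iv.start + j1)
                    end = min(sizes[iv.chrom], iv.end + j2)
                    if end <= start:
                        end = start + 1
                    peak = Peak(
                        interval=GenomicInterval(iv.chrom, start, end),
                        name=f"{e.name}|{mark}|rep{r + 1}",
                        score=0,
                        fold_enrichment=round(fold, 3),
                        neg_log10_p=5.0,
                        neg_log10_q=3.0,
                        summit_offset=(end - start) // 2,
                    )
                    out[species][mark][r].append(peak)
                    emitted_rows.append({"element": e.name, "species": species,
                                         "mark": mark, "rep": r + 1})
    for species in out:
        for mark in MARKS:
            for r in range(n_reps):
                out[species][mark][r].sort(
                    key=lambda p: (p.interval.chrom, p.interval.start)
                )
    emitted = pd.DataFrame(emitted_rows, columns=["element", "species", "mark", "rep"])
    return out, emitted


def _stage_profiles(timepoints: int) -> np.ndarray:
    """Interpolate the planted cluster profiles to ``timepoints`` stages."""
    src = np.linspace(0, 1, _CLUSTER_PROFILES.shape[1])
    dst = np.linspace(0, 1, timepoints)
    return np.vstack([np.interp(dst, src, row) for row in _CLUSTER_PROFILES])


def make_expression(
    truth: SyntheticTruth,
    timepoints: int = 6,
    reps: int = 3,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    lib_size: int = 2_000_000,
    n_background: int = 200,
) -> dict:
    """Negative-binomial count matrices per species with the planted temporal
    cluster patterns and species-specific high-expression genes.

    Counts ~ NB(mean = lib_size-scaled planted TPM profile, dispersion
    ``nb_dispersion``; Poisson at dispersion 0). Species-specific genes are
    planted flat at 50 TPM in species A and 0.05 TPM in species B at every
    stage. Flat genes (cluster -1) have a constant profile and are excluded
    by the fold-change filter by construction.

    ``n_background`` filler genes (ids ``bg{species}_*``, flat profile)
    absorb the residual transcript mass so that planted TPM values are the
    realized TPM values: without them the handful of planted genes would be
    renormalized to absurd levels and the 1/10-TPM thresholds would lose
    their meaning.

    Returns {"A": ExpressionMatrix, "B": ExpressionMatrix}.
    """
    if timepoints < 2 or reps < 2:
        raise ValidationError("need timepoints >= 2 and reps >= 2")
    if nb_dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    from .expression import ExpressionMatrix

    profiles = _stage_profiles(timepoints)
    gt = truth.gene_truth.set_index("gene_id_a")
    lengths_a = {g.gene_id: g.gene_length for g in truth.genes_a}
    lengths_b = {g.gene_id: g.gene_length for g in truth.genes_b}
    out = {}
    for species in ("A", "B"):
        rng = _rng(seed, f"expr_{species}")
        genes = truth.genes_a if species == "A" else truth.genes_b
        lengths = lengths_a if species == "A" else lengths_b
        gene_ids = [g.gene_id for g in genes]
        # planted TPM (gene x stage)
        tpm = np.zeros((len(genes), timepoints))
        for i, g in enumerate(genes):
            if species == "A":
                row = gt.loc[g.gene_id]
            else:
                a_id = g.ortholog_id
                if a_id is None or a_id not in gt.index:
                    # B-only gene: moderate flat expression
                    tpm[i] = 15.0
                    continue
                row = gt.loc[a_id]
            cluster = int(row["cluster"])
            base = 20.0
            prof = np.ones(timepoints) if cluster < 0 else profiles[cluster]
            prof = prof / prof.mean()
            if bool(row["species_specific"]):
                tpm[i] = 50.0 if species == "A" else 0.05
            else:
                tpm[i] = base * prof
        # background pool: flat genes absorbing the residual transcript mass
        # so planted TPM values are realized TPM values
        residual = 1e6 - tpm.sum(axis=0)
        if (residual <= 0).any():
            raise ValidationError("planted TPM exceeds 1e6; reduce gene count")
        bg_ids = [f"bg{species}_{i:04d}" for i in range(n_background)]
        bg_tpm = np.tile(residual / n_background, (n_background, 1))
        tpm = np.vstack([tpm, bg_tpm])
        gene_ids = gene_ids + bg_ids
        for b in bg_ids:
            lengths = {**lengths, b: 1_000}
        length_vec = np.array([lengths[g] for g in gene_ids], dtype=float)
        counts = np.zeros((len(gene_ids), timepoints * reps), dtype=int)
        cols = []
        meta_rows = []
        for t in range(timepoints):
            # expected read share: TPM weighted by gene length
            w = tpm[:, t] * length_vec
            mu = lib_size * w / w.sum()
            for r in range(reps):
                if nb_dispersion > 0:
                    lam = rng.gamma(shape=1.0 / nb_dispersion,
                                    scale=mu * nb_dispersion)
                else:
                    lam = mu
                col = rng.poisson(lam)
                cname = f"{species}_t{t}_r{r + 1}"
                cols.append(cname)
                meta_rows.append({"sample": cname, "species": species,
                                  "stage": f"t{t}", "replicate": f"r{r + 1}"})
                counts[:, t * reps + r] = col
        counts_df = pd.DataFrame(counts, index=gene_ids, columns=cols)
        samples = pd.DataFrame(meta_rows).set_index("sample")
        out[species] = ExpressionMatrix(
            counts=counts_df,
            gene_lengths=pd.Series(length_vec, index=gene_ids),
            samples=samples,
        )
    return out


# ---------------------------------------------------------------------------
# File emission (the `simulate` CLI surface)
# ---------------------------------------------------------------------------


def write_simulation(
    outdir: str | Path,
    seed: int,
    jitter_sd: float = 5.0,
    dropout: float = 0.1,
    timepoints: int = 6,
    reps: int = 3,
    nb_dispersion: float = 0.05,
    **genome_kwargs,
) -> dict:
    """Generate a full input set on disk: narrowPeak replicates, chain files,
    gene tables, count matrices, and the truth manifest. Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes_a, genes_b, chains_ab, chains_ba, truth = make_genome_pair(
        seed=seed, **genome_kwargs
    )
    peaks, emitted = make_peak_replicates(truth, jitter_sd, dropout, seed)
    expr = make_expression(truth, timepoints, reps, nb_dispersion, seed)

    paths: dict = {"outdir": str(outdir)}
    write_gene_models(genes_a, outdir / "genes_A.tsv")
    write_gene_models(genes_b, outdir / "genes_B.tsv")
    write_chain(chains_ab, outdir / "chain_A_to_B.chain")
    write_chain(chains_ba, outdir / "chain_B_to_A.chain")
    paths["genes"] = {"A": str(outdir / "genes_A.tsv"), "B": str(outdir / "genes_B.tsv")}
    paths["chains"] = {"AB": str(outdir / "chain_A_to_B.chain"),
                       "BA": str(outdir / "chain_B_to_A.chain")}
    paths["peaks"] = {}
    for species, marks in peaks.items():
        for mark, rep_lists in marks.items():
            for r, plist in enumerate(rep_lists):
                p = outdir / f"peaks_{species}_{mark}_rep{r + 1}.narrowPeak"
                write_narrowpeak(plist, p)
                paths["peaks"][f"{species}_{mark}_rep{r + 1}"] = str(p)
    paths["counts"] = {}
    for species, em in expr.items():
        cp = outdir / f"counts_{species}.tsv"
        em.counts.to_csv(cp, sep="\t", index_label="gene_id")
        em.samples.to_csv(outdir / f"samples_{species}.tsv", sep="\t")
        em.gene_lengths.rename("gene_length").to_csv(
            outdir / f"gene_lengths_{species}.tsv", sep="\t", index_label="gene_id"
        )
        paths["counts"][species] = str(cp)

    manifest = pd.DataFrame(
        [
            {
                "element": e.name,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "true_class": e.true_class,
                "conservation": e.conservation,
                "partner_chrom": e.partner.chrom if e.partner else "",
                "partner_start": e.partner.start if e.partner else -1,
                "partner_end": e.partner.end if e.partner else -1,
                "gene_a": e.gene_a,
            }
            for e in truth.elements
        ]
    )
    manifest.to_csv(outdir / "truth_elements.tsv", sep="\t", index=False)
    emitted.to_csv(outdir / "truth_emitted_peaks.tsv", sep="\t", index=False)
    truth.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    paths["truth"] = {
        "elements": str(outdir / "truth_elements.tsv"),
        "emitted": str(outdir / "truth_emitted_peaks.tsv"),
        "genes": str(outdir / "truth_genes.tsv"),
    }
    return paths
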