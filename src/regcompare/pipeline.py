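"""End-to-end orchestration: consensus -> classify -> crossmap -> express ->
temporal -> enrichment, plus planted-truth recovery evaluation for synthetic
runs.

Stage outputs are plain TSV/BED-like tables so any stage can be rerun or
inspected standalone; a JSON manifest records the seed, every threshold and
per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import enrichment as _enrichment
from . import expression as _expression
from . import liftover as _liftover
from . import peaks as _peaks
from . import temporal as _temporal
from .io_formats import (
    GenomicInterval,
    ValidationError,
    read_chain,
    read_gene_models,
    read_narrowpeak,
)

log = logging.getLogger("regcompare")


@dataclass
class Thresholds:
    """Every tunable the pipeline uses, with its default."""

    min_frac: float = 0.5            # replicate overlap fraction
    recip_frac: float = 0.5          # K4/K27 reciprocal merge fraction
    max_tss_distance: int = 3000     # high-confidence promoter band
    max_link_distance: int = 1_000_000
    min_match: float = 0.95          # liftover aligned-fraction cutoff
    summit_width: int = 100          # width of lifted summit windows
    tpm_expressed: float = 1.0
    tpm_high: float = 10.0
    tpm_low: float = 1.0
    cpm: float = 2.0
    cpm_min_reps: int = 2
    logfc: float = 2.0
    k_clusters: int = 5
    k_min: int = 1
    k_max: int = 10
    fuzzifier: float = 2.0
    fdr: float = 0.01


def central_window(iv: GenomicInterval, width: int = 100,
                   chrom_size: int | None = None) -> GenomicInterval:
    """Fixed-width window on the interval midpoint (the lifted unit when no
    summit is tracked for a merged element)."""
    mid = iv.start + iv.length // 2
    lo = max(0, mid - width // 2)
    hi = mid + width // 2
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    if lo >= hi:
        raise ValidationError("window off chromosome")
    return GenomicInterval(iv.chrom, lo, hi)


def classify_species(
    peaks_by_mark: dict, genes: list, thresholds: Thresholds
) -> tuple[list, list]:
    """Consensus + classification + nearest-gene annotation + promoter
    distance filter for one species.

    ``peaks_by_mark`` maps mark -> [rep1 peaks, rep2 peaks]. Returns
    (kept elements, distal promoters)."""
    consensus = {
        mark: _peaks.reproducible_peaks(reps[0], reps[1], thresholds.min_frac)
        for mark, reps in peaks_by_mark.items()
    }
    elements = _classify.classify_elements(
        consensus.get("H3K4me3", []), consensus.get("H3K27ac", []),
        thresholds.recip_frac,
    )
    elements = [e for e in elements if e.element_class != "ambiguous"]
    elements = _classify.annotate_nearest_gene(elements, genes)
    kept, distal = _classify.filter_promoters(elements, thresholds.max_tss_distance)
    return kept, distal


def crossmap(
    elements_A: list,
    chains_ab: list,
    chains_ba: list,
    genes_A: list,
    elements_B_by_stage: dict,
    thresholds: Thresholds,
    chrom_sizes_a: dict | None = None,
    full_length: bool = False,
) -> pd.DataFrame:
    """Lift species-A elements to B (100-bp central windows by default),
    apply the reciprocal same-nearest-gene filter, and call conserved vs
    species-specific activity per stage.

    Returns the conserved_activity table joined with the reciprocal-filter
    status; elements failing the reciprocal filter are labeled unalignable.
    """
    units = {}
    for e in elements_A:
        iv = e.interval
        if not full_length:
            size = chrom_sizes_a.get(iv.chrom) if chrom_sizes_a else None
            iv = central_window(iv, thresholds.summit_width, size)
        units[e.name] = iv

    lifted_elements = [
        _classify.RegulatoryElement(
            interval=units[e.name], element_class=e.element_class, marks=e.marks,
            mean_fold_enrichment=e.mean_fold_enrichment, name=e.name,
            nearest_gene=e.nearest_gene, tss_distance=e.tss_distance,
        )
        for e in elements_A
    ]
    kept, recip_report = _liftover.reciprocal_filter(
        lifted_elements, chains_ab, chains_ba, genes_A, thresholds.min_match
    )
    kept_names = {e.name for e in kept}
    mapped = {
        e.name: _liftover.map_interval(
            units[e.name], chains_ab, thresholds.min_match, e.name
        )
        for e in elements_A
        if e.name in kept_names
    }
    activity = _liftover.conserved_activity(elements_A, mapped, elements_B_by_stage)
    activity = activity.merge(
        recip_report[["element", "status", "mapped_fraction"]], on="element"
    )
    return activity


def run_full(config: dict) -> dict:
    """Run the pipeline end to end from a config dict (paths + thresholds +
    seed). Writes staged TSV artifacts and a run manifest under
    ``config['outdir']``; returns a summary dict with key result tables.

    Required config keys: outdir, seed, peaks (species -> mark -> [rep
    paths]), genes (species -> path), chains ({AB, BA}), counts (species ->
    {counts, samples, gene_lengths}). Optional: thresholds (overrides).
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds(**config.get("thresholds", {}))
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "thresholds": asdict(thresholds),
                      "stages": {}, "inputs": {}}

    def checksum(path: str) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    stage = "inputs"
    try:
        peaks = {
            sp: {mark: [read_narrowpeak(p) for p in repaths]
                 for mark, repaths in marks.items()}
            for sp, marks in config["peaks"].items()
        }
        genes = {sp: read_gene_models(p) for sp, p in config["genes"].items()}
        chains_ab = read_chain(config["chains"]["AB"])
        chains_ba = read_chain(config["chains"]["BA"])
        for sp, marks in config["peaks"].items():
            for mark, repaths in marks.items():
                for p in repaths:
                    manifest["inputs"][str(p)] = checksum(p)

        stage = "consensus/classify"
        elements = {}
        distal = {}
        for sp in peaks:
            elements[sp], distal[sp] = classify_species(
                peaks[sp], genes[sp], thresholds
            )
            manifest["stages"][f"classify_{sp}"] = {
                "elements": len(elements[sp]), "distal_promoters": len(distal[sp]),
            }
            pd.DataFrame(
                [
                    {
                        "chrom": e.interval.chrom, "start": e.interval.start,
                        "end": e.interval.end, "name": e.name,
                        "class": e.element_class, "marks": ",".join(sorted(e.marks)),
                        "nearest_gene": e.nearest_gene, "tss_distance": e.tss_distance,
                        "mean_fold": e.mean_fold_enrichment,
                    }
                    for e in elements[sp]
                ]
            ).to_csv(outdir / f"elements_{sp}.tsv", sep="\t", index=False)

        stage = "crossmap"
        chrom_sizes_a = {c.t_name: c.t_size for c in chains_ab}
        activity = crossmap(
            elements["A"], chains_ab, chains_ba, genes["A"],
            {"B": elements["B"]}, thresholds, chrom_sizes_a,
        )
        activity.to_csv(outdir / "conservation_A_in_B.tsv", sep="\t", index=False)
        manifest["stages"]["crossmap"] = {
            "conserved": int((activity["label"] == "conserved").sum()),
            "speciesA_specific": int((activity["label"] == "speciesA_specific").sum()),
            "unalignable": int((activity["label"] == "unalignable").sum()),
        }

        stage = "express"
        summaries = {}
        expressed = {}
        for sp, paths in config["counts"].items():
            counts = pd.read_csv(paths["counts"], sep="\t", index_col="gene_id")
            samples = pd.read_csv(paths["samples"], sep="\t", index_col="sample")
            lengths = pd.read_csv(
                paths["gene_lengths"], sep="\t", index_col="gene_id"
            )["gene_length"]
            em = _expression.ExpressionMatrix(counts, lengths, samples)
            summaries[sp] = (em, _expression.normalize(em))
            first_stage = sorted(samples["stage"].unique())[0]
            cols = em.sample_ids(sp, first_stage)
            expressed[sp] = _expression.reproducibly_expressed(
                summaries[sp][1].tpm[cols], thresholds.tpm_expressed
            )
            manifest["stages"][f"express_{sp}"] = {"reproducibly_expressed": len(expressed[sp])}

        orth = {g.gene_id: g.ortholog_id for g in genes["A"] if g.ortholog_id}
        orth_genes_A = [g for g in genes["A"] if g.ortholog_id]
        links = _classify.link_to_genes(
            elements["A"], orth_genes_A, thresholds.max_link_distance
        )
        links.to_csv(outdir / "links_A.tsv", sep="\t", index=False)
        report = _expression.element_expression_report(links, expressed["A"])
        em_B, summ_B = summaries["B"]
        stages_B = sorted(em_B.samples["stage"].unique())
        tpm_B_by_stage = {s: summ_B.tpm[em_B.sample_ids("B", s)] for s in stages_B}
        em_A, summ_A = summaries["A"]
        first_A = sorted(em_A.samples["stage"].unique())[0]
        tpm_A = summ_A.tpm[em_A.sample_ids("A", first_A)]
        specific, spec_report = _expression.species_specific_genes(
            tpm_A, tpm_B_by_stage, orth, thresholds.tpm_high, thresholds.tpm_low
        )
        manifest["stages"]["species_specific"] = spec_report

        stage = "temporal"
        cpm_B = summ_B.cpm
        keep = set()
        for s in stages_B:
            keep |= _expression.cpm_filter(
                cpm_B[em_B.sample_ids("B", s)], thresholds.cpm, thresholds.cpm_min_reps
            )
        mean_cpm = pd.DataFrame(
            {s: cpm_B[em_B.sample_ids("B", s)].mean(axis=1) for s in stages_B}
        ).loc[sorted(keep)]
        dyn = _temporal.dynamic_genes(mean_cpm, thresholds.logfc)
        profiles = _temporal.zscale(np.log2(mean_cpm.loc[sorted(dyn)] + 1))
        clustering = _temporal.cmeans(
            profiles, k=thresholds.k_clusters, m=thresholds.fuzzifier, seed=seed
        )
        members, centers = _temporal.cluster_report(clustering, profiles)
        members.to_csv(outdir / "clusters_B.tsv", sep="\t", index=False)
        centers.to_csv(outdir / "cluster_centers_B.tsv", sep="\t")
        manifest["stages"]["temporal"] = {
            "dynamic_genes": len(dyn), "clustered": len(members),
            "converged": bool(clustering.converged),
        }

        stage = "enrichment"
        clusters = {
            int(c): set(sub["gene_id"]) for c, sub in members.groupby("cluster")
        }
        universe = set(members["gene_id"])
        query = {orth[g] for g in expressed["A"] if g in orth} & universe
        if query and query != universe:
            enr = _enrichment.cluster_enrichment(query, clusters, universe)
        else:
            # degenerate 2x2 margins (query empty or saturating the universe)
            enr = []
        pd.DataFrame([asdict(r) for r in enr]).to_csv(
            outdir / "cluster_enrichment.tsv", sep="\t", index=False
        )
        manifest["stages"]["enrichment"] = {
            "clusters_tested": len(enr),
            "query_size": len(query),
            "universe_size": len(universe),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "elements": elements,
        "activity": activity,
        "expressed": expressed,
        "species_specific": specific,
        "expression_report": report,
        "clustering": clustering,
        "cluster_members": members,
        "cluster_enrichment": enr,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# Planted-truth evaluation
# ---------------------------------------------------------------------------


def _consensus_survives(emitted: pd.DataFrame, element: str, species: str,
                        mark: str, n_reps: int = 2) -> bool:
    sub = emitted[
        (emitted["element"] == element)
        & (emitted["species"] == species)
        & (emitted["mark"] == mark)
    ]
    return sub["rep"].nunique() >= n_reps


def evaluate_recovery(
    truth, emitted: pd.DataFrame, elements_A: list, activity: pd.DataFrame
) -> dict:
    """Compare recovered element classes and conservation labels with the
    planted truth.

    Evaluation is conditional on the evidence that survived replicate
    dropout: an element enters the class denominator when the peaks its
    class definition requires are present in both replicates (H3K27ac for
    enhancers, H3K4me3 for promoters, in species A), and enters the
    conservation denominator when additionally its species-B partner peaks
    survived (for planted-conserved elements). Jitter noise is always
    unconditional.
    """
    pred_by_truth: dict[str, object] = {}
    for e in elements_A:
        for t in truth.elements:
            if t.conservation == "speciesB_specific":
                continue
            if e.interval.overlap(t.interval) > 0:
                prev = pred_by_truth.get(t.name)
                if prev is None or e.interval.overlap(t.interval) > prev.interval.overlap(t.interval):
                    pred_by_truth[t.name] = e

    label_by_element = dict(zip(activity["element"], activity["label"]))
    class_total = class_correct = 0
    cons_total = cons_correct = 0
    for t in truth.elements:
        if t.conservation == "speciesB_specific":
            continue
        need_mark = "H3K27ac" if t.true_class == "enhancer" else "H3K4me3"
        if not _consensus_survives(emitted, t.name, "A", need_mark):
            continue
        pred = pred_by_truth.get(t.name)
        class_total += 1
        if pred is not None and pred.element_class == t.true_class:
            class_correct += 1
        else:
            continue
        if t.conservation == "conserved" and not _consensus_survives(
            emitted, t.name, "B", need_mark
        ):
            continue
        cons_total += 1
        want = "conserved" if t.conservation == "conserved" else "speciesA_specific"
        got = label_by_element.get(pred.name)
        if got == want:
            cons_correct += 1
    return {
        "class_total": class_total,
        "class_correct": class_correct,
        "class_accuracy": class_correct / class_total if class_total else float("nan"),
        "conservation_total": cons_total,
        "conservation_correct": cons_correct,
        "conservation_accuracy": cons_correct / cons_total if cons_total else float("nan"),
    }
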