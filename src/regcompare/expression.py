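"""Count normalization (TPM/CPM) and the expression threshold rules used to
define reproducibly expressed, filtered, and species-specific gene sets.

Conventions
-----------
* TPM_gs = 1e6 * (count_gs / length_g) / sum_g(count_gs / length_g)
* CPM_gs = 1e6 * count_gs / sum_g count_gs
* "reproducibly expressed": TPM strictly > threshold in EVERY replicate
* CPM filter: CPM strictly > threshold in at least ``min_reps`` replicates
* species-specific high expression: mean TPM > ``high`` in species A and
  mean TPM < ``low`` at every species-B stage (means over replicates)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ValidationError


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with gene lengths and sample metadata.

    ``samples`` is indexed by the count-matrix columns and carries columns
    species, stage, replicate (unique within species/stage).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValidationError(f"genes without lengths: {list(missing)[:5]}")
        if (self.gene_lengths.loc[self.counts.index] <= 0).any():
            raise ValidationError("gene lengths must be > 0")
        if not self.samples.index.equals(self.counts.columns):
            raise ValidationError("sample metadata index must match count columns")
        dup = self.samples.duplicated(subset=["species", "stage", "replicate"])
        if dup.any():
            raise ValidationError("replicate labels not unique within species/stage")

    def sample_ids(self, species: str, stage: str | None = None) -> list[str]:
        mask = self.samples["species"] == species
        if stage is not None:
            mask &= self.samples["stage"] == stage
        return list(self.samples.index[mask])


@dataclass
class ExpressionSummary:
    tpm: pd.DataFrame
    cpm: pd.DataFrame


def normalize(em: ExpressionMatrix) -> ExpressionSummary:
    """TPM and CPM per sample. Both columns sum to 1e6 by construction."""
    counts = em.counts.astype(float)
    zero = counts.sum(axis=0) == 0
    if zero.any():
        raise ValidationError(f"all-zero sample(s): {list(counts.columns[zero])}")
    lengths = em.gene_lengths.loc[counts.index].astype(float)
    rate = counts.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    cpm = counts.div(counts.sum(axis=0), axis=1) * 1e6
    return ExpressionSummary(tpm=tpm, cpm=cpm)


def reproducibly_expressed(tpm: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Genes with TPM strictly above ``threshold`` in every replicate column."""
    if tpm.shape[1] < 2:
        raise ValidationError("need >= 2 replicates")
    mask = (tpm > threshold).all(axis=1)
    return set(tpm.index[mask])


def cpm_filter(cpm: pd.DataFrame, threshold: float = 2.0, min_reps: int = 2) -> set[str]:
    """Genes with CPM strictly above ``threshold`` in >= ``min_reps`` of the
    replicate columns (the low-expression filter)."""
    if cpm.shape[1] < min_reps:
        raise ValidationError("fewer replicates than min_reps")
    mask = (cpm > threshold).sum(axis=1) >= min_reps
    return set(cpm.index[mask])


def species_specific_genes(
    tpm_A: pd.DataFrame,
    tpm_B_by_stage: dict[str, pd.DataFrame],
    ortholog_map: dict[str, str],
    high: float = 10.0,
    low: float = 1.0,
) -> tuple[set[str], dict]:
    """Genes highly expressed only in species A.

    A gene (by its species-A id) is included iff its mean TPM over A
    replicates exceeds ``high`` AND its ortholog's mean TPM is below ``low``
    at every species-B stage. Genes without a one-to-one ortholog are
    excluded and counted in the report.
    """
    mean_A = tpm_A.mean(axis=1)
    means_B = {s: df.mean(axis=1) for s, df in tpm_B_by_stage.items()}
    out: set[str] = set()
    missing = 0
    for gene in tpm_A.index:
        orth = ortholog_map.get(gene)
        if orth is None:
            missing += 1
            continue
        if mean_A[gene] <= high:
            continue
        if all(orth in mb.index and mb[orth] < low for mb in means_B.values()):
            out.add(gene)
    report = {"missing_ortholog": missing, "n_species_specific": len(out)}
    return out, report


def element_expression_report(
    link_table: pd.DataFrame, expressed_genes: set[str]
) -> dict:
    """Summarize the correspondence between regulatory elements and expressed
    genes.

    Returns a dict with, per element class, the fraction of elements linked
    to a gene in ``expressed_genes``; plus a per-gene table categorizing each
    expressed gene as linked to enhancer only / promoter only / both /
    neither, and the fraction of expressed genes near any element.
    """
    frac_by_class: dict[str, float] = {}
    for cls, sub in link_table.groupby("element_class"):
        hit = sub["gene_id"].isin(expressed_genes)
        frac_by_class[cls] = float(hit.mean()) if len(sub) else float("nan")

    linked = link_table[link_table["linked"] & link_table["gene_id"].notna()]
    enh_genes = set(linked.loc[linked["element_class"] == "enhancer", "gene_id"])
    pro_genes = set(linked.loc[linked["element_class"] == "promoter", "gene_id"])
    rows = []
    for g in sorted(expressed_genes):
        e, p = g in enh_genes, g in pro_genes
        cat = "both" if (e and p) else "enhancer_only" if e else "promoter_only" if p else "neither"
        rows.append({"gene_id": g, "category": cat})
    gene_table = pd.DataFrame(rows, columns=["gene_id", "category"])
    near_any = float((gene_table["category"] != "neither").mean()) if len(gene_table) else float("nan")
    return {
        "linked_expressed_fraction": frac_by_class,
        "gene_table": gene_table,
        "expressed_near_element_fraction": near_any,
    }


def linked_fraction(n_linked: int, n_total: int) -> float:
    """Percentage of a count over a total (helper for printed-table ratios)."""
    if n_total <= 0:
        raise ValidationError("total must be positive")
    if not (0 <= n_linked <= n_total):
        raise ValidationError("numerator outside [0, total]")
    return 100.0 * n_linked / n_total
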