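"""Interval mapping between genomes through UCSC alignment chains, the
reciprocal same-nearest-gene filter, and conserved-activity calls.

Mapping follows liftOver semantics: among chains covering the source
interval, the highest-scoring one wins (ties broken by chain id); bases
falling in aligned blocks are projected to query coordinates, and the mapped
interval is the [min, max) hull of the projected bases on the forward strand
of the query. An interval maps only if at least ``min_match`` of its bases
are aligned (default 0.95, the liftOver same-species default).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import RegulatoryElement, nearest_tss
from .io_formats import ChainAlignment, GenomicInterval, GeneModel, ValidationError

STATUS_MAPPED = "mapped"
STATUS_UNMAPPED = "unmapped"
STATUS_SPLIT = "split"


@dataclass(frozen=True)
class MappedElement:
    source_id: str
    status: str
    mapped_fraction: float
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.status == STATUS_MAPPED and self.interval is None:
            raise ValidationError(f"{self.source_id}: mapped without an interval")


def _project_through(
    iv: GenomicInterval, chain: ChainAlignment
) -> tuple[int, int | None, int | None]:
    """Project iv through one chain.

    Returns (aligned_bases, q_min_fwd, q_max_fwd_exclusive) with query
    coordinates converted to the forward strand.
    """
    aligned = 0
    qmin: int | None = None
    qmax: int | None = None  # chain-frame, exclusive
    t = chain.t_start
    q = chain.q_start
    for b in chain.blocks:
        lo = max(iv.start, t)
        hi = min(iv.end, t + b.size)
        if lo < hi:
            aligned += hi - lo
            q_lo = q + (lo - t)
            q_hi = q + (hi - t)
            qmin = q_lo if qmin is None else min(qmin, q_lo)
            qmax = q_hi if qmax is None else max(qmax, q_hi)
        t += b.size + b.dt
        q += b.size + b.dq
    if aligned == 0:
        return 0, None, None
    if chain.q_strand == "+":
        return aligned, qmin, qmax
    # reverse frame -> forward: [qmin, qmax) maps to [q_size - qmax, q_size - qmin)
    return aligned, chain.q_size - qmax, chain.q_size - qmin


def map_interval(
    iv: GenomicInterval,
    chains: list[ChainAlignment],
    min_match: float = 0.95,
    source_id: str = "",
) -> MappedElement:
    """Map one interval to the query genome through the best covering chain."""
    if not (0 < min_match <= 1):
        raise ValidationError(f"min_match must be in (0, 1], got {min_match}")
    covering = [
        c
        for c in chains
        if c.t_name == iv.chrom and c.t_start < iv.end and c.t_end > iv.start
    ]
    if not covering:
        return MappedElement(source_id, STATUS_UNMAPPED, 0.0)
    best = max(covering, key=lambda c: (c.score, -c.chain_id))
    aligned, q_lo, q_hi = _project_through(iv, best)
    frac = aligned / iv.length
    if aligned == 0 or frac < min_match:
        return MappedElement(source_id, STATUS_UNMAPPED, frac)
    strand = "+" if best.q_strand == "+" else "-"
    return MappedElement(
        source_id,
        STATUS_MAPPED,
        frac,
        GenomicInterval(best.q_name, q_lo, q_hi, strand),
    )


def reciprocal_filter(
    elements_A: list[RegulatoryElement],
    chain_AB: list[ChainAlignment],
    chain_BA: list[ChainAlignment],
    genes_A: list[GeneModel],
    min_match: float = 0.95,
) -> tuple[list[RegulatoryElement], pd.DataFrame]:
    """Keep elements that survive reciprocal liftover with the same
    nearest-gene call.

    An element is alignable iff A->B and B->A both map with status=mapped and
    the round-trip interval's nearest gene (within species A) equals the
    element's own nearest-gene annotation.

    Returns (kept elements, per-element report with columns element, status,
    mapped_fraction, roundtrip_gene, kept).
    """
    kept: list[RegulatoryElement] = []
    rows = []
    for e in elements_A:
        fwd = map_interval(e.interval, chain_AB, min_match, e.name)
        status, rt_gene, keep = fwd.status, None, False
        if fwd.status == STATUS_MAPPED:
            back = map_interval(fwd.interval, chain_BA, min_match, e.name)
            if back.status != STATUS_MAPPED:
                status = f"roundtrip_{back.status}"
            else:
                rt_gene, _ = nearest_tss(back.interval, genes_A)
                if rt_gene is not None and rt_gene == e.nearest_gene:
                    keep = True
                    status = "alignable"
                else:
                    status = "nearest_gene_changed"
        if keep:
            kept.append(e)
        rows.append(
            {
                "element": e.name,
                "status": status,
                "mapped_fraction": fwd.mapped_fraction,
                "roundtrip_gene": rt_gene,
                "kept": keep,
            }
        )
    report = pd.DataFrame(
        rows, columns=["element", "status", "mapped_fraction", "roundtrip_gene", "kept"]
    )
    return kept, report


def conserved_activity(
    elements_A: list[RegulatoryElement],
    mapped: dict[str, MappedElement],
    elements_B_by_stage: dict[str, list[RegulatoryElement]],
) -> pd.DataFrame:
    """Per-element, per-stage conserved-activity calls.

    An element is conserved at a stage iff its mapped interval overlaps
    (>= 1 bp) any element of the SAME class at that stage in species B.
    An element mapped to B but conserved at no stage is species-A-specific
    (alignable but without a matching peak); unmapped elements are
    unalignable. Every element receives exactly one overall label.

    Returns a DataFrame with one row per element: columns element, class,
    one boolean column per stage, and ``label`` in
    {conserved, speciesA_specific, unalignable}.
    """
    stages = list(elements_B_by_stage)
    rows = []
    for e in elements_A:
        m = mapped.get(e.name)
        row: dict = {"element": e.name, "element_class": e.element_class}
        if m is None or m.status != STATUS_MAPPED:
            for s in stages:
                row[s] = False
            row["label"] = "unalignable"
        else:
            any_hit = False
            for s in stages:
                hit = any(
                    b.element_class == e.element_class
                    and m.interval.overlap(b.interval) >= 1
                    for b in elements_B_by_stage[s]
                )
                row[s] = hit
                any_hit = any_hit or hit
            row["label"] = "conserved" if any_hit else "speciesA_specific"
        rows.append(row)
    return pd.DataFrame(rows, columns=["element", "element_class", *stages, "label"])


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap target and query of a plus/plus chain (used to build mutually
    inverse chain pairs)."""
    if chain.q_strand != "+" or chain.t_strand != "+":
        raise ValidationError("invert_chain supports plus/plus chains only")
    from .io_formats import ChainBlock

    blocks = tuple(ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks)
    inv = ChainAlignment(
        score=chain.score,
        t_name=chain.q_name,
        t_size=chain.q_size,
        t_strand="+",
        t_start=chain.q_start,
        t_end=chain.q_end,
        q_name=chain.t_name,
        q_size=chain.t_size,
        q_strand="+",
        q_start=chain.t_start,
        q_end=chain.t_end,
        chain_id=chain.chain_id,
        blocks=blocks,
    )
    inv.validate()
    return inv
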