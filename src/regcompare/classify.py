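"""Co-occupancy classification of consensus peaks into putative promoters and
enhancers, nearest-TSS annotation, and the TSS-distance promoter filter.

Classes are operational, defined purely by histone-mark co-occupancy:

* H3K4me3 with no H3K27ac overlap            -> promoter (single mark)
* H3K27ac with no H3K4me3 overlap            -> enhancer
* H3K4me3/H3K27ac pair overlapping by >= ``recip_frac`` of BOTH peak lengths
  -> merged into one double-marked promoter (union span, mean signal)
* overlapping pairs failing the reciprocal test -> both labeled ambiguous and
  excluded from downstream sets (conservative: keeps both class definitions
  literally true)

The reciprocal test is inclusive (>=) so boundary cases are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .io_formats import GenomicInterval, GeneModel, ValidationError
from .peaks import ConsensusPeak, _UnionFind

H3K4ME3 = "H3K4me3"
H3K27AC = "H3K27ac"


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    element_class: str  # enhancer | promoter | ambiguous
    marks: frozenset
    mean_fold_enrichment: float
    name: str = ""
    nearest_gene: str | None = None
    tss_distance: int | None = None

    def __post_init__(self) -> None:
        if self.element_class == "enhancer" and self.marks != frozenset({H3K27AC}):
            raise ValidationError(f"{self.name}: enhancer must carry only {H3K27AC}")
        if self.element_class == "promoter" and H3K4ME3 not in self.marks:
            raise ValidationError(f"{self.name}: promoter must carry {H3K4ME3}")


def _reciprocal(a: ConsensusPeak, b: ConsensusPeak, frac: float) -> bool:
    ov = a.interval.overlap(b.interval)
    return ov >= frac * a.interval.length and ov >= frac * b.interval.length


def classify_elements(
    k4: list[ConsensusPeak], k27: list[ConsensusPeak], recip_frac: float = 0.5
) -> list[RegulatoryElement]:
    """Classify H3K4me3 and H3K27ac consensus peaks into regulatory elements.

    Every input peak is accounted for exactly once (as a solo element, as a
    member of a merged double-marked promoter, or as ambiguous).
    """
    if not (0 < recip_frac <= 1):
        raise ValidationError(f"recip_frac must be in (0, 1], got {recip_frac}")
    peaks = list(k4) + list(k27)
    n4 = len(k4)
    uf = _UnionFind(len(peaks))
    overlapping = [False] * len(peaks)
    merged = [False] * len(peaks)

    by_chrom: dict[str, list[int]] = {}
    for j in range(n4, len(peaks)):
        by_chrom.setdefault(peaks[j].interval.chrom, []).append(j)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda j: peaks[j].interval.start)

    for i in range(n4):
        a = peaks[i]
        for j in by_chrom.get(a.interval.chrom, ()):
            b = peaks[j]
            if b.interval.start >= a.interval.end:
                break
            if a.interval.overlap(b.interval) > 0:
                overlapping[i] = overlapping[j] = True
                if _reciprocal(a, b, recip_frac):
                    uf.union(i, j)
                    merged[i] = merged[j] = True

    elements: list[RegulatoryElement] = []
    counter = 0

    def next_name(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}_{counter}"

    # merged double-marked promoters
    components: dict[int, list[int]] = {}
    for idx, flag in enumerate(merged):
        if flag:
            components.setdefault(uf.find(idx), []).append(idx)
    for _root, members in sorted(
        components.items(),
        key=lambda kv: (
            peaks[kv[1][0]].interval.chrom,
            min(peaks[m].interval.start for m in kv[1]),
        ),
    ):
        ms = [peaks[m] for m in members]
        elements.append(
            RegulatoryElement(
                interval=GenomicInterval(
                    ms[0].interval.chrom,
                    min(p.interval.start for p in ms),
                    max(p.interval.end for p in ms),
                ),
                element_class="promoter",
                marks=frozenset({H3K4ME3, H3K27AC}),
                mean_fold_enrichment=sum(p.mean_fold_enrichment for p in ms) / len(ms),
                name=next_name("promoter"),
            )
        )

    # solo and ambiguous peaks
    for i, p in enumerate(peaks):
        if merged[i]:
            continue
        mark = H3K4ME3 if i < n4 else H3K27AC
        if overlapping[i]:
            cls = "ambiguous"
            marks = frozenset({mark})
        elif mark == H3K4ME3:
            cls = "promoter"
            marks = frozenset({H3K4ME3})
        else:
            cls = "enhancer"
            marks = frozenset({H3K27AC})
        elements.append(
            RegulatoryElement(
                interval=p.interval,
                element_class=cls,
                marks=marks,
                mean_fold_enrichment=p.mean_fold_enrichment,
                name=next_name(cls),
            )
        )
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return elements


def nearest_tss(
    interval: GenomicInterval, genes: list[GeneModel]
) -> tuple[str | None, int | None]:
    """Nearest gene by TSS distance, with the sign convention that the
    distance is 0 when the element contains the TSS and negative when the TSS
    lies 5' of the element along the gene's strand. Ties by smallest gene_id.
    """
    best: tuple[int, str, int] | None = None  # (|d|, gene_id, signed d)
    for g in genes:
        if g.chrom != interval.chrom:
            continue
        if interval.start <= g.tss < interval.end:
            d = 0
        elif g.tss < interval.start:
            mag = interval.start - g.tss
            d = -mag if g.strand == "+" else mag
        else:
            mag = g.tss - interval.end
            d = mag if g.strand == "+" else -mag
        key = (abs(d), g.gene_id, d)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[1], best[2]


def annotate_nearest_gene(
    elements: list[RegulatoryElement], genes: list[GeneModel]
) -> list[RegulatoryElement]:
    """Attach nearest gene and signed TSS distance to every element."""
    out = []
    for e in elements:
        gid, d = nearest_tss(e.interval, genes)
        out.append(replace(e, nearest_gene=gid, tss_distance=d))
    return out


def filter_promoters(
    elements: list[RegulatoryElement], max_tss_distance: int = 3000
) -> tuple[list[RegulatoryElement], list[RegulatoryElement]]:
    """Partition promoters by distance to the nearest TSS.

    Promoters with |tss_distance| <= ``max_tss_distance`` (inclusive) are
    high-confidence; the remainder is returned separately, not discarded.
    Enhancers (and ambiguous elements) pass through in the first list
    untouched. The partition is exhaustive and disjoint.
    """
    kept: list[RegulatoryElement] = []
    distal: list[RegulatoryElement] = []
    for e in elements:
        if e.element_class != "promoter":
            kept.append(e)
            continue
        if e.tss_distance is not None and abs(e.tss_distance) <= max_tss_distance:
            kept.append(e)
        else:
            distal.append(e)
    return kept, distal


def link_to_genes(
    elements: list[RegulatoryElement],
    genes: list[GeneModel],
    max_link_distance: int = 1_000_000,
) -> pd.DataFrame:
    """Element-to-gene link table: each element is linked to its nearest gene
    from ``genes`` iff the TSS lies within ``max_link_distance`` bp. Pass an
    ortholog-filtered gene list for cross-species use.

    Returns a DataFrame with columns element, element_class, gene_id,
    tss_distance, linked.
    """
    rows = []
    for e in elements:
        gid, d = nearest_tss(e.interval, genes)
        linked = gid is not None and abs(d) <= max_link_distance
        rows.append(
            {
                "element": e.name,
                "element_class": e.element_class,
                "gene_id": gid if linked else None,
                "tss_distance": d,
                "linked": linked,
            }
        )
    return pd.DataFrame(rows, columns=["element", "element_class", "gene_id", "tss_distance", "linked"])
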