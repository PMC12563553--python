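"""Readers and writers for the interval, alignment and annotation formats the
pipeline consumes, plus the shared coordinate conventions.

All internal coordinates are 0-based half-open (BED convention). GFF3 input is
converted on read: a gene on the + strand has its TSS at ``start - 1``, a gene
on the - strand at ``end - 1``. Minus-strand chain query coordinates are kept
in chain-native (reverse-complement) frame exactly as parsed; conversion to
forward-strand coordinates is an explicit helper so it can be tested in
isolation.

Readers reject malformed records rather than silently repairing them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

VALID_STRANDS = frozenset({"+", "-", "."})


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A record violates a semantic invariant (coordinates, arithmetic, ids)."""


# ---------------------------------------------------------------------------
# Core interval types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span: ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A narrowPeak record: an enriched interval with summit and signal."""

    interval: GenomicInterval
    name: str
    score: int = 0
    fold_enrichment: float = 0.0
    neg_log10_p: float = -1.0
    neg_log10_q: float = -1.0
    summit_offset: int = -1  # bp from start; -1 = no summit called

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise ValidationError(f"peak {self.name}: fold_enrichment < 0")
        if not (self.summit_offset == -1 or 0 <= self.summit_offset < self.interval.length):
            raise ValidationError(
                f"peak {self.name}: summit_offset {self.summit_offset} outside "
                f"[0, {self.interval.length})"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when no summit called."""
        if self.summit_offset == -1:
            return self.interval.start + self.interval.length // 2
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    """Gene-level annotation carrying only what the pipeline needs: the TSS
    (for nearest-gene assignment) and the gene length (for TPM)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_length: int
    ortholog_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS")
        if self.gene_length <= 0:
            raise ValidationError(f"gene {self.gene_id}: gene_length must be > 0")


# ---------------------------------------------------------------------------
# Chain alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped block followed by gaps of dt bp in target, dq bp in query."""

    size: int
    dt: int = 0
    dq: int = 0


@dataclass(frozen=True)
class ChainAlignment:
    """Gapped co-linear alignment between a target and a query genome
    (UCSC chain semantics). Minus-strand query coordinates are stored in
    chain-native reversed frame; use :meth:`q_forward` to convert."""

    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: tuple[ChainBlock, ...]

    def validate(self) -> None:
        sizes = sum(b.size for b in self.blocks)
        dts = sum(b.dt for b in self.blocks)
        dqs = sum(b.dq for b in self.blocks)
        if self.blocks and (self.blocks[-1].dt or self.blocks[-1].dq):
            raise ValidationError(f"chain {self.chain_id}: last block carries gaps")
        if sizes + dts != self.t_end - self.t_start:
            raise ValidationError(
                f"chain {self.chain_id}: target span {self.t_end - self.t_start} "
                f"!= block sum {sizes + dts}"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise ValidationError(
                f"chain {self.chain_id}: query span {self.q_end - self.q_start} "
                f"!= block sum {sizes + dqs}"
            )

    def q_forward(self, pos: int) -> int:
        """Convert a chain-frame query base position to forward-strand
        coordinates: identity on '+', ``q_size - 1 - pos`` on '-'."""
        if self.q_strand == "+":
            return pos
        return self.q_size - 1 - pos


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:g}"


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Columns 7, 8, 9 and 10 populate fold_enrichment, -log10(p), -log10(q)
    and summit_offset respectively. Coordinates are preserved exactly.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
                )
            try:
                chrom, start, end, name, score, strand = (
                    fields[0], int(fields[1]), int(fields[2]), fields[3],
                    int(float(fields[4])), fields[5],
                )
                fold, logp, logq, summit = (
                    float(fields[6]), float(fields[7]), float(fields[8]), int(fields[9]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    name=name,
                    score=score,
                    fold_enrichment=fold,
                    neg_log10_p=logp,
                    neg_log10_q=logq,
                    summit_offset=summit,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom, str(iv.start), str(iv.end), p.name, str(p.score),
                        iv.strand, _fmt(p.fold_enrichment), _fmt(p.neg_log10_p),
                        _fmt(p.neg_log10_q), str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

_CHAIN_HEADER_FIELDS = 13


def read_chain(path: str | Path) -> list[ChainAlignment]:
    """Read a UCSC chain file, validating block arithmetic per chain."""
    chains: list[ChainAlignment] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        parts = line.split()
        if parts[0] != "chain" or len(parts) != _CHAIN_HEADER_FIELDS:
            raise FormatError(f"{path}:{i + 1}: expected chain header, got {line!r}")
        try:
            (score, t_name, t_size, t_strand, t_start, t_end,
             q_name, q_size, q_strand, q_start, q_end, chain_id) = (
                int(parts[1]), parts[2], int(parts[3]), parts[4], int(parts[5]),
                int(parts[6]), parts[7], int(parts[8]), parts[9], int(parts[10]),
                int(parts[11]), int(parts[12]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 1}: {exc}") from exc
        i += 1
        blocks: list[ChainBlock] = []
        terminated = False
        while i < n:
            bl = lines[i].strip()
            if not bl:
                i += 1
                terminated = True
                break
            bparts = bl.split()
            if bparts[0] == "chain":
                break
            try:
                nums = [int(x) for x in bparts]
            except ValueError as exc:
                raise FormatError(f"{path}:{i + 1}: bad block line {bl!r}") from exc
            if len(nums) == 3:
                blocks.append(ChainBlock(nums[0], nums[1], nums[2]))
            elif len(nums) == 1:
                blocks.append(ChainBlock(nums[0]))
                terminated = True
                i += 1
                break
            else:
                raise FormatError(f"{path}:{i + 1}: block line must have 1 or 3 fields")
            i += 1
        if not blocks or not terminated:
            raise FormatError(f"{path}: chain {chain_id}: truncated block list")
        chain = ChainAlignment(
            score=score, t_name=t_name, t_size=t_size, t_strand=t_strand,
            t_start=t_start, t_end=t_end, q_name=q_name, q_size=q_size,
            q_strand=q_strand, q_start=q_start, q_end=q_end,
            chain_id=chain_id, blocks=tuple(blocks),
        )
        chain.validate()
        chains.append(chain)
    return chains


def write_chain(chains: Iterable[ChainAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3 gene records or flat TSV)
# ---------------------------------------------------------------------------

_GENE_TSV_HEADER = ["gene_id", "chrom", "strand", "tss", "gene_length", "ortholog_id"]


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` records only) or from the flat
     6-column TSV the pipeline writes. Dispatch is on content: a header line
    starting with ``gene_id`` selects TSV, otherwise GFF3.

    GFF3 1-based inclusive coordinates are converted to the 0-based half-open
    convention: TSS = start - 1 on '+', end - 1 on '-'.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.split("\t")[0].strip() == "gene_id":
        return _read_gene_tsv(path)
    return _read_gene_gff3(path)


def _read_gene_tsv(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_TSV_HEADER:
            raise FormatError(f"{path}: bad gene-table header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            gene_id, chrom, strand, tss, length, orth = fields
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id, chrom=chrom, strand=strand,
                    tss=int(tss), gene_length=int(length),
                    ortholog_id=orth if orth not in ("", ".", "NA") else None,
                )
            )
    return genes


def _read_gene_gff3(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: unknown strand {strand!r}")
            start_i, end_i = int(start), int(end)
            if start_i < 1 or end_i < start_i:
                raise ValidationError(f"{path}:{lineno}: bad GFF3 span {start}-{end}")
            attr = _parse_gff_attributes(attrs)
            gene_id = attr.get("ID") or attr.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene record lacks ID attribute")
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            tss = start_i - 1 if strand == "+" else end_i - 1
            genes.append(
                GeneModel(
                    gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                    gene_length=end_i - start_i + 1,
                    ortholog_id=attr.get("ortholog"),
                )
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TSV_HEADER) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [g.gene_id, g.chrom, g.strand, str(g.tss), str(g.gene_length),
                     g.ortholog_id or ""]
                )
                + "\n"
            )
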