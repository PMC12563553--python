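"""Replicate-reproducibility filtering and peak summarization.

An enriched region is considered reproducible when it overlaps a peak in the
other biological replicate by at least ``min_frac`` of its length (default
50%). Peaks from the two replicates that mutually satisfy the rule are
union-merged (transitively, so chained overlaps A1-B1-A2 collapse into one
region) into a single consensus peak whose signal is the mean fold enrichment
of its members and whose summit comes from the strongest member.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GenomicInterval, Peak, ValidationError


@dataclass(frozen=True)
class ConsensusPeak:
    """A reproducible peak supported by >= 2 replicate peaks."""

    interval: GenomicInterval
    mean_fold_enrichment: float
    support: int
    summit_offset: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.support < 2:
            raise ValidationError(f"consensus peak {self.name}: support < 2")
        if self.mean_fold_enrichment < 0:
            raise ValidationError(f"consensus peak {self.name}: negative fold")

    @property
    def summit(self) -> int:
        if self.summit_offset == -1:
            return self.interval.start + self.interval.length // 2
        return self.interval.start + self.summit_offset


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _mutual(a: Peak, b: Peak, min_frac: float) -> bool:
    ov = a.interval.overlap(b.interval)
    return ov >= min_frac * a.interval.length and ov >= min_frac * b.interval.length


def reproducible_peaks(
    rep1: list[Peak], rep2: list[Peak], min_frac: float = 0.5
) -> list[ConsensusPeak]:
    """Consensus peaks from two biological replicates.

    A pair (a from rep1, b from rep2) mutually satisfies the reproducibility
    rule when their overlap is >= ``min_frac`` of both peak lengths. All peaks
    connected through such pairs are union-merged into one consensus peak.
    Peaks with no mutual partner are dropped.

    The operation is symmetric in its replicate arguments and the output is
    sorted by (chrom, start).
    """
    if not (0 < min_frac <= 1):
        raise ValidationError(f"min_frac must be in (0, 1], got {min_frac}")
    all_peaks = list(rep1) + list(rep2)
    n1 = len(rep1)
    uf = _UnionFind(len(all_peaks))

    # sweep per chromosome: rep2 sorted by start, advance a window pointer
    by_chrom: dict[str, list[int]] = {}
    for j in range(n1, len(all_peaks)):
        by_chrom.setdefault(all_peaks[j].interval.chrom, []).append(j)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda j: all_peaks[j].interval.start)

    paired = [False] * len(all_peaks)
    for i in range(n1):
        a = all_peaks[i]
        for j in by_chrom.get(a.interval.chrom, ()):
            b = all_peaks[j]
            if b.interval.start >= a.interval.end:
                break
            if _mutual(a, b, min_frac):
                uf.union(i, j)
                paired[i] = paired[j] = True

    components: dict[int, list[int]] = {}
    for idx, flag in enumerate(paired):
        if flag:
            components.setdefault(uf.find(idx), []).append(idx)

    out: list[ConsensusPeak] = []
    for k, (_root, members) in enumerate(sorted(
        components.items(),
        key=lambda kv: (
            all_peaks[kv[1][0]].interval.chrom,
            min(all_peaks[m].interval.start for m in kv[1]),
        ),
    )):
        ms = [all_peaks[m] for m in members]
        chrom = ms[0].interval.chrom
        start = min(p.interval.start for p in ms)
        end = max(p.interval.end for p in ms)
        best = max(ms, key=lambda p: (p.fold_enrichment, p.name))
        out.append(
            ConsensusPeak(
                interval=GenomicInterval(chrom, start, end),
                mean_fold_enrichment=sum(p.fold_enrichment for p in ms) / len(ms),
                support=len(ms),
                summit_offset=best.summit - start,
                name=f"consensus_{k + 1}",
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return out


def summit_window(
    peak: ConsensusPeak | Peak, width: int = 100, chrom_size: int | None = None
) -> GenomicInterval:
    """The ``width``-bp window centred on the peak summit, clipped at
    chromosome bounds. When no summit was called the interval midpoint is
    used (MACS2 emits -1 in that case)."""
    if width < 2 or width % 2 != 0:
        raise ValidationError(f"width must be even and >= 2, got {width}")
    summit = peak.summit
    lo = summit - width // 2
    hi = summit + width // 2
    lo_c = max(0, lo)
    hi_c = hi if chrom_size is None else min(hi, chrom_size)
    if hi_c <= 0 or (chrom_size is not None and lo_c >= chrom_size) or lo_c >= hi_c:
        raise ValidationError(
            f"summit window [{lo}, {hi}) falls entirely off the chromosome"
        )
    return GenomicInterval(peak.interval.chrom, lo_c, hi_c)
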