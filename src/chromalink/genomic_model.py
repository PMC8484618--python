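"""Genomic geometry for the accessibility analysis.

All coordinates are 0-based, half-open (BED convention).  The module houses
the interval substrate (:class:`GenomicInterval`), gene models with derived
promoter windows and introns, summit-derived accessibility peaks, and the
coordinate operations the rest of the pipeline relies on: summit extension,
peak merging, promoter classification, distances to gene bodies, exon/intron
assignment of peak summits, and contact-domain containment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Peak",
    "ContactDomain",
    "extend_summits",
    "merge_peak_regions",
    "peak_set_from_summits",
    "classify_peak",
    "classify_peaks",
    "distance_to_gene_body",
    "assign_exon_intron",
    "contact_domain_containment",
    "mean_exonic_fraction",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "SUMMIT_FLANK",
]

#: Promoter window, in transcription orientation, relative to the first TSS.
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100

#: Summits are extended by this many bp on either side (final width 200 bp).
SUMMIT_FLANK = 100


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene: identity, body interval, strand, and exon structure.

    The first TSS is derived from the strand (``body.start`` on ``+``,
    ``body.end - 1`` on ``-``); introns are the gene body minus the exons.
    """

    gene_id: str
    body: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        prev_end = self.body.start - 1
        for exon in self.exons:
            if not self.body.contains(exon):
                raise ValueError(f"exon {exon} outside gene body of {self.gene_id}")
            if exon.start <= prev_end:
                raise ValueError(f"exons of {self.gene_id} unsorted or overlapping")
            prev_end = exon.end

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def tss(self) -> int:
        """First transcription start site (strand-aware)."""
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gene body minus exons, in genomic order."""
        out = []
        cursor = self.body.start
        for exon in self.exons:
            if exon.start > cursor:
                out.append(GenomicInterval(self.chrom, cursor, exon.start))
            cursor = exon.end
        if cursor < self.body.end:
            out.append(GenomicInterval(self.chrom, cursor, self.body.end))
        return tuple(out)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def promoter_window(
        self,
        upstream: int = PROMOTER_UPSTREAM,
        downstream: int = PROMOTER_DOWNSTREAM,
        chrom_size: int | None = None,
    ) -> GenomicInterval:
        """Strand-aware promoter window around the first TSS.

        ``upstream``/``downstream`` are measured in transcription
        orientation; on the ``+`` strand this is genomic
        ``[tss - upstream, tss + downstream + 1)`` and the mirror image on
        ``-``.  The window is clamped at chromosome boundaries.
        """
        tss = self.tss
        if self.strand == "+":
            lo, hi = tss - upstream, tss + downstream + 1
        else:
            lo, hi = tss - downstream, tss + upstream + 1
        lo = max(lo, 0)
        if chrom_size is not None:
            hi = min(hi, chrom_size)
        return GenomicInterval(self.chrom, lo, hi)


@dataclass(frozen=True)
class Peak:
    """A summit-derived accessible-chromatin interval."""

    peak_id: str
    interval: GenomicInterval
    summit: int
    peak_class: str = "unclassified"
    member_summits: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.interval.contains_position(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval of {self.peak_id}"
            )


@dataclass(frozen=True)
class ContactDomain:
    """A chromatin contact domain consumed from external loop data."""

    interval: GenomicInterval


def extend_summits(
    summits: Sequence[tuple[str, int]],
    chrom_sizes: Mapping[str, int],
    flank: int = SUMMIT_FLANK,
) -> list[Peak]:
    """Extend each summit by ``flank`` bp on either side.

    Intervals are clamped to ``[0, chrom_size)`` so edge peaks may be
    narrower than ``2 * flank``.  Unknown chromosomes raise ``KeyError``.
    """
    peaks = []
    for i, (chrom, pos) in enumerate(summits):
        if chrom not in chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        if not (0 <= pos < size):
            raise ValueError(f"summit {pos} outside {chrom} [0, {size})")
        iv = GenomicInterval(chrom, max(pos - flank, 0), min(pos + flank, size))
        peaks.append(
            Peak(f"summit_{i:06d}", iv, summit=pos, member_summits=(pos,))
        )
    return peaks


def merge_peak_regions(peaks: Iterable[Peak]) -> list[Peak]:
    """Union-merge overlapping or bookended peak intervals.

    The output is sorted, pairwise disjoint and covers exactly the union of
    the input.  Each merged peak records its member summits; its
    representative summit is the median member.  Idempotent and invariant to
    input order.
    """
    by_pos = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    merged: list[Peak] = []
    out: list[tuple[str, int, int, list[int]]] = []
    for p in by_pos:
        iv = p.interval
        summits = list(p.member_summits) or [p.summit]
        if out and out[-1][0] == iv.chrom and iv.start <= out[-1][2]:
            chrom, start, end, mem = out[-1]
            out[-1] = (chrom, start, max(end, iv.end), mem + summits)
        else:
            out.append((iv.chrom, iv.start, iv.end, summits))
    for i, (chrom, start, end, mem) in enumerate(out):
        mem = sorted(mem)
        summit = mem[(len(mem) - 1) // 2]
        merged.append(
            Peak(
                f"peak_{i:06d}",
                GenomicInterval(chrom, start, end),
                summit=summit,
                member_summits=tuple(mem),
            )
        )
    return merged


def peak_set_from_summits(
    summits: Sequence[tuple[str, int]],
    chrom_sizes: Mapping[str, int],
    flank: int = SUMMIT_FLANK,
) -> list[Peak]:
    """Summit extension followed by union-merge: the complete peak set."""
    return merge_peak_regions(extend_summits(summits, chrom_sizes, flank))


class _PromoterIndex:
    """Per-chromosome promoter-window index for fast overlap queries."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        chrom_sizes: Mapping[str, int] | None = None,
    ):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        windows: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            size = chrom_sizes.get(g.chrom) if chrom_sizes else None
            w = g.promoter_window(chrom_size=size)
            windows.setdefault(g.chrom, []).append((w.start, w.end))
        for chrom, ws in windows.items():
            ws.sort()
            starts = np.array([a for a, _ in ws])
            ends = np.array([b for _, b in ws])
            # prefix max of ends enables "any window with start < e, end > s"
            self._by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, maxends = self._by_chrom[chrom]
        idx = int(np.searchsorted(starts, end, side="left"))
        return idx > 0 and maxends[idx - 1] > start


def classify_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    mode: str = "overlap",
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Classify each peak as promoter or non-promoter.

    A peak is a promoter element iff it overlaps any gene's promoter window
    (``mode='overlap'``, default) or its summit falls inside one
    (``mode='summit'``).  Returns new :class:`Peak` records; the input is
    untouched.
    """
    if mode not in ("overlap", "summit"):
        raise ValueError(f"unknown classification mode {mode!r}")
    index = _PromoterIndex(genes, chrom_sizes)
    out = []
    for p in peaks:
        if mode == "summit":
            hit = index.overlaps(p.interval.chrom, p.summit, p.summit + 1)
        else:
            hit = index.overlaps(p.interval.chrom, p.interval.start, p.interval.end)
        out.append(replace(p, peak_class="promoter" if hit else "non_promoter"))
    return out


def classify_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    mode: str = "overlap",
    chrom_sizes: Mapping[str, int] | None = None,
) -> str:
    """Promoter/non-promoter class of a single peak (see :func:`classify_peaks`)."""
    return classify_peaks([peak], genes, mode=mode, chrom_sizes=chrom_sizes)[0].peak_class


def distance_to_gene_body(peak: Peak, gene: GeneModel) -> tuple[int, bool]:
    """Unsigned bp distance from a peak to a gene body.

    Returns ``(0, True)`` when the peak interval overlaps the body, else the
    gap between nearest edges and ``False``.  Different chromosomes are a
    caller error.
    """
    iv, body = peak.interval, gene.body
    if iv.chrom != body.chrom:
        raise ValueError(
            f"peak on {iv.chrom} vs gene on {body.chrom}: distance undefined"
        )
    if iv.overlaps(body):
        return 0, True
    if iv.end <= body.start:
        return body.start - iv.end, False
    return iv.start - body.end, False


def assign_exon_intron(peak: Peak, gene: GeneModel) -> str:
    """Locate a peak's summit within a gene: exonic, intronic or outside."""
    if peak.interval.chrom != gene.chrom:
        return "outside"
    pos = peak.summit
    if not gene.body.contains_position(pos):
        return "outside"
    for exon in gene.exons:
        if exon.contains_position(pos):
            return "exonic"
    return "intronic"


def contact_domain_containment(
    interval: GenomicInterval, domains: Iterable[ContactDomain]
) -> bool:
    """True iff the interval lies fully inside at least one contact domain."""
    return any(d.interval.contains(interval) for d in domains)


def mean_exonic_fraction(genes: Iterable[GeneModel]) -> float:
    """Mean, over genes, of exonic length divided by gene-body length.

    This is the expected exonic fraction used as the null rate in the
    exon/intron enrichment binomial test.
    """
    fracs = [g.exonic_length / g.body.length for g in genes]
    if not fracs:
        raise ValueError("empty gene collection")
    return float(np.mean(fracs))
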