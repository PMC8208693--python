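"""Mobile-genetic-element proximity to a focal gene.

MGEs (plasmids, prophages, viruses, transposons) are the vehicles of
horizontal transfer, so finding putative MGE matches within a fixed flank
(default 5 kb) of a candidate gene supports an HGT call. Distances follow
the terminal-base convention: from the gene's 3'-terminal base to the
element's proximal base on the 3' side, and from the 5'-terminal base on
the 5' side, counted as the simple coordinate difference (adjacency = 1);
overlaps are distance 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .gc_profile import fold_ratio
from .io_formats import GenomicFeature

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

DEFAULT_FLANK = 5000


@dataclass
class MGERecord:
    """One putative MGE match with its genomic location."""

    element_id: str
    element_class: str  # plasmid | prophage | virus | other
    host: str
    match_length: int
    evalue: float
    percent_identity: float
    location: GenomicFeature
    gc_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.match_length < 1:
            raise ValueError("match_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class ProximityResult:
    gene_id: str
    element_id: str
    side: str  # upstream | downstream (gene-strand sense)
    distance: int
    within_flank: bool
    overlaps: bool = False


def flank_windows(gene: GenomicFeature, contig_length: int,
                  flank: int = DEFAULT_FLANK,
                  ) -> tuple[Optional[tuple[int, int]], Optional[tuple[int, int]]]:
    """(upstream, downstream) 1-based inclusive windows, clipped to the contig.

    Upstream/downstream are defined on the gene's strand (5' side =
    upstream); a window squeezed to nothing at a contig edge is None.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if gene.end > contig_length:
        raise ValueError("gene extends beyond the contig")
    low = (max(1, gene.start - flank), gene.start - 1) if gene.start > 1 else None
    high = ((gene.end + 1, min(contig_length, gene.end + flank))
            if gene.end < contig_length else None)
    if low is not None and low[0] > low[1]:
        low = None
    if high is not None and high[0] > high[1]:
        high = None
    if gene.strand == "+":
        return low, high
    return high, low


def mge_distance(gene: GenomicFeature, mge: GenomicFeature) -> ProximityResult:
    """Terminal-base distance between a gene and an element on one contig."""
    if gene.seq_id != mge.seq_id:
        raise ValueError(
            f"gene on {gene.seq_id!r} but element on {mge.seq_id!r}")
    element_id = mge.attributes.get("element_id", mge.feature_type)
    gene_id = gene.attributes.get("ID", gene.feature_type)
    if mge.start <= gene.end and gene.start <= mge.end:
        # overlap: side by element midpoint relative to the gene's strand
        mid_high = (mge.start + mge.end) / 2 >= (gene.start + gene.end) / 2
        side = (DOWNSTREAM if mid_high == (gene.strand == "+") else UPSTREAM)
        return ProximityResult(gene_id, element_id, side, 0, True, overlaps=True)
    if mge.start > gene.end:  # element on the high-coordinate side
        distance = mge.start - gene.end
        side = DOWNSTREAM if gene.strand == "+" else UPSTREAM
    else:  # element on the low-coordinate side
        distance = gene.start - mge.end
        side = UPSTREAM if gene.strand == "+" else DOWNSTREAM
    return ProximityResult(gene_id, element_id, side, distance, True)


def proximity_report(gene: GenomicFeature, mges: Iterable[MGERecord],
                     genome_gc: Optional[float] = None,
                     flank: int = DEFAULT_FLANK,
                     ) -> list[tuple[ProximityResult, Optional[float]]]:
    """Elements within the flank, nearest first, with G+C fold ratios.

    Each returned row pairs the proximity result with the element's
    G+C fold ratio versus the genome (None when either G+C is unknown).
    The species-level "any MGE within flank" flag is simply ``bool(result)``.
    """
    rows = []
    for mge in mges:
        prox = mge_distance(gene, mge.location)
        prox.within_flank = prox.distance <= flank
        if not prox.within_flank:
            continue
        prox.element_id = mge.element_id
        ratio = (fold_ratio(mge.gc_percent, genome_gc)
                 if mge.gc_percent is not None and genome_gc else None)
        rows.append((prox, ratio))
    rows.sort(key=lambda r: (r[0].distance, r[0].element_id))
    return rows
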