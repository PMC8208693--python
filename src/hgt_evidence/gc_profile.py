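"""G+C composition analysis: mol% G+C, donor-vs-host affinity, fold ratios.

A horizontally acquired gene tends to retain the base composition of the
donor genome for a long time after transfer, so a gene whose mol% G+C sides
with the putative donor rather than with its host genome is compositional
evidence for transfer. IUPAC ambiguity codes contribute their expected G+C
fraction (S=1, W=0, R=N=0.5, ...) so that mol% is defined for every valid
nucleotide sequence; with plain ACGT input this reduces to the direct count.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import gc_fraction

from .io_formats import GenomicFeature, SequenceRecord

DONOR_CONSISTENT = "donor_consistent"
HOST_CONSISTENT = "host_consistent"
TIE = "tie"


@dataclass
class GCStats:
    length: int
    gc_count: float

    @property
    def mol_percent(self) -> float:
        return 100.0 * self.gc_count / self.length


@dataclass
class GCAffinity:
    gene_gc: float
    host_genome_gc: float
    donor_gene_gc: float
    delta_host: float
    delta_donor: float
    verdict: str


def gc_content(seq: SequenceRecord | str) -> GCStats:
    """Weighted G+C tally of a nucleotide sequence (full length denominator)."""
    if isinstance(seq, SequenceRecord):
        if seq.alphabet != "nt":
            raise ValueError("gc_content requires a nucleotide record")
        residues = seq.residues
    else:
        residues = SequenceRecord(id="_", residues=str(seq).upper(),
                                  alphabet="nt").residues
    if not residues:
        raise ValueError("gc_content of an empty sequence is undefined")
    frac = gc_fraction(residues, ambiguous="weighted")
    return GCStats(length=len(residues), gc_count=frac * len(residues))


def gc_affinity(gene_gc: float, host_genome_gc: float,
                donor_gene_gc: float) -> GCAffinity:
    """Does the gene's composition side with the donor or the host?

    Verdict is donor_consistent iff |gene − donor| < |gene − host|, with
    exact ties reported as tie.
    """
    for name, v in (("gene_gc", gene_gc), ("host_genome_gc", host_genome_gc),
                    ("donor_gene_gc", donor_gene_gc)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} out of [0,100]: {v!r}")
    delta_host = abs(gene_gc - host_genome_gc)
    delta_donor = abs(gene_gc - donor_gene_gc)
    if delta_donor < delta_host:
        verdict = DONOR_CONSISTENT
    elif delta_host < delta_donor:
        verdict = HOST_CONSISTENT
    else:
        verdict = TIE
    return GCAffinity(gene_gc, host_genome_gc, donor_gene_gc,
                      delta_host, delta_donor, verdict)


def fold_ratio(mge_gc: float, genome_gc: float) -> float:
    """G+C ratio of a mobile element to its resident genome (e.g. 86.4/30.4 → 2.8)."""
    if genome_gc <= 0:
        raise ValueError("genome G+C must be positive")
    return mge_gc / genome_gc


def gene_gc(genome: SequenceRecord, feature: GenomicFeature) -> GCStats:
    """mol% G+C of a feature's span (1-based inclusive); strand-invariant."""
    if feature.end > len(genome.residues):
        raise ValueError(
            f"feature {feature.start}..{feature.end} exceeds sequence "
            f"{genome.id!r} of length {len(genome.residues)}"
        )
    return gc_content(genome.residues[feature.start - 1:feature.end])


def sliding_window_gc(seq: SequenceRecord | str, window: int,
                      step: int) -> list[tuple[int, GCStats, bool]]:
    """G+C in sliding windows at 1-based starts 1, 1+step, ...

    Returns (start, stats, is_partial); the trailing partial window (if any)
    is included and flagged.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    n = len(residues)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    out = []
    start = 1
    while start <= n:
        chunk = residues[start - 1:start - 1 + window]
        out.append((start, gc_content(chunk), len(chunk) < window))
        if start - 1 + window >= n:
            break
        start += step
    return out
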