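"""Fully synthetic HGT scenarios with known truth labels.

Emulates the data regime of a donor/recipient transfer study: a recipient
genome of one base composition, a donor genome of a very different one, a
focal gene whose composition matches the donor (when a transfer happened),
a homology table in which the donor orthologue scores a far smaller E value
than the best same-lineage hit, a gene tree in which the transferred leaf
sits sister to the donor leaf, and MGE annotations inside/outside the
flanking windows. Everything is a pure function of the scenario (seed
included), so every pipeline stage is testable without any downloads.

The E-value model is Karlin–Altschul-shaped, E = K·m·n·exp(−λ·S), with a
per-residue match/mismatch score S = L·(s_match·p + s_mismatch·(1−p)) where
p is the fractional identity. Only monotonicity in identity and coverage of
the realistic E-value range matter here — the alien index consumes E
values, not alignments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .io_formats import (GenomicFeature, HomologyHit, SequenceRecord,
                         write_blast6, write_fasta, write_gff3)

#: a perfect instantiation of the PAP I consensus signature (11 residues)
MOTIF_INSTANCE = "LVGKRFRLAHI"
_MOTIF_CODONS = ("CTG", "GTG", "GGC", "AAA", "CGT", "TTT",
                 "CGT", "CTG", "GCG", "CAC", "ATT")


@dataclass
class EvalueModel:
    """Parameters of the identity → E-value map."""

    K: float = 0.041
    lam: float = 0.267
    m: int = 450
    n: int = 450
    s_match: float = 2.0
    s_mismatch: float = -0.3

    def evalue(self, percent_identity: float, gene_length: int) -> float:
        p = percent_identity / 100.0
        score = gene_length * (self.s_match * p + self.s_mismatch * (1 - p))
        log_e = math.log(self.K * self.m * self.n) - self.lam * score
        return math.exp(log_e) if log_e > -700 else 0.0


@dataclass
class TransferScenario:
    """Parameter bundle driving one synthetic dataset, with truth labels.

    Defaults mirror the dramatic published regime: a low-G+C recipient
    (≈33 mol%, cf. an Empedobacter-like genome) acquiring a gene from a
    high-G+C donor (≈71 mol%), donor identity 80–100 %, same-lineage
    identity ~29–38 %.
    """

    seed: int = 0
    recipient_gc: float = 33.0
    donor_gc: float = 71.0
    genome_length: int = 100_000
    gene_length: int = 900
    transfer: bool = True
    motif_embedded: bool = True
    evalue_model: EvalueModel = field(default_factory=EvalueModel)
    tree_leaves: int = 8
    mge_within: int = 2
    mge_outside: int = 1
    flank: int = 5000

    def __post_init__(self) -> None:
        if not (0 <= self.recipient_gc <= 100 and 0 <= self.donor_gc <= 100):
            raise ValueError("G+C targets must be in [0,100]")
        if self.gene_length % 3:
            raise ValueError("gene_length must be a multiple of 3")
        if self.gene_length > self.genome_length / 10:
            raise ValueError("gene_length must be <= genome_length/10")
        if self.tree_leaves < 4:
            raise ValueError("tree_leaves must be >= 4")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus writers for the on-disk formats."""

    scenario: TransferScenario
    genomes: list            # [recipient, donor] SequenceRecord (nt)
    features: list           # GenomicFeature: focal gene, donor gene, MGEs
    proteins: list           # SequenceRecord (aa), one per tree leaf
    homology: list           # HomologyHit rows (query = focal protein)
    tree_newick: str
    truth: dict

    def write(self, outdir) -> dict:
        """Write FASTA/GFF3/TSV/Newick/JSON files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genomes": outdir / "genomes.fasta",
            "proteins": outdir / "proteins.fasta",
            "features": outdir / "features.gff3",
            "homology": outdir / "homology.tsv",
            "tree": outdir / "tree.nwk",
            "truth": outdir / "truth.json",
        }
        with open(paths["genomes"], "w") as fh:
            write_fasta(self.genomes, fh)
        with open(paths["proteins"], "w") as fh:
            write_fasta(self.proteins, fh)
        with open(paths["features"], "w") as fh:
            write_gff3(self.features, fh)
        with open(paths["homology"], "w") as fh:
            write_blast6(self.homology, fh)
        paths["tree"].write_text(self.tree_newick + "\n")
        paths["truth"].write_text(json.dumps(self.truth, indent=2) + "\n")
        return {k: str(v) for k, v in paths.items()}


def generate_genome(length: int, gc_target: float, seed: int,
                    seq_id: str = "genome") -> SequenceRecord:
    """Random genome with bases drawn i.i.d. at the target G+C."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_target <= 100:
        raise ValueError("gc_target must be in [0,100]")
    rng = np.random.default_rng(seed)
    g = gc_target / 200.0
    a = (100.0 - gc_target) / 200.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[a, g, g, a])
    return SequenceRecord(id=seq_id, residues="".join(bases), alphabet="nt")


def _random_gene(rng: np.random.Generator, length: int, gc_target: float,
                 embed_motif: bool) -> str:
    """Random gene with exact target composition (up to base granularity).

    A shuffled fixed-composition base multiset keeps the gene's mol% G+C
    pinned to the target, so compositional affinity verdicts depend on the
    scenario, not on sampling noise. Embedding the signature motif's codons
    perturbs the composition by well under one percentage point at typical
    gene lengths.
    """
    n_gc = round(length * gc_target / 100)
    n_g = n_gc // 2
    n_a = (length - n_gc) // 2
    bases = np.array(list("G" * n_g + "C" * (n_gc - n_g)
                          + "A" * n_a + "T" * (length - n_gc - n_a)))
    seq = "".join(rng.permutation(bases))
    if embed_motif:
        n_codons = length // 3
        at = int(rng.integers(1, n_codons - len(_MOTIF_CODONS)))
        seq = (seq[:3 * at] + "".join(_MOTIF_CODONS)
               + seq[3 * (at + len(_MOTIF_CODONS)):])
    return seq


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACDEFGHIKLMNPQRSTVWY")),
                              size=length))


def make_tree(scenario: TransferScenario) -> str:
    """Newick gene tree over donor-clade and recipient-clade leaves.

    With ``transfer=True`` the focal leaf is grafted sister to the donor
    leaf on short branches, so the donor is guaranteed nearest by patristic
    distance; otherwise the focal leaf nests inside the recipient clade.
    Supports are drawn in [700, 1000] so every clade survives collapse at
    the conventional 700/1000 threshold.
    """
    rng = np.random.default_rng((scenario.seed, 2))
    n_each = max(2, scenario.tree_leaves // 2)
    donor_leaves = ["donor_pap"] + [f"donor_rel_{i}" for i in range(1, n_each)]
    recip_leaves = (["recipient_tnt"]
                    + [f"recipient_rel_{i}" for i in range(1, n_each)])

    def blen() -> float:
        return float(np.round(rng.uniform(0.2, 0.5), 4))

    def support() -> int:
        return int(rng.integers(700, 1001))

    def join(subs: list[str]) -> str:
        subs = list(subs)
        while len(subs) > 1:
            i, j = sorted(rng.choice(len(subs), size=2, replace=False))
            b = subs.pop(j)
            a = subs.pop(i)
            subs.append(f"({a},{b}){support()}:{blen()}")
        return subs[0]

    graft_target = "donor_pap" if scenario.transfer else "recipient_tnt"
    donor_tips = [f"{l}:{blen()}" for l in donor_leaves]
    recip_tips = [f"{l}:{blen()}" for l in recip_leaves]
    query_pair = f"(query_gene:0.01,{graft_target}:0.01){support()}:{blen()}"
    if scenario.transfer:
        donor_tips[0] = query_pair
    else:
        recip_tips[0] = query_pair
    # join() leaves a branch length on the merged clade; the root children
    # get fixed stem lengths instead
    donor_clade = join(donor_tips).rsplit(":", 1)[0]
    recip_clade = join(recip_tips).rsplit(":", 1)[0]
    return f"({donor_clade}:0.5,{recip_clade}:0.5);"


def simulate_transfer(scenario: TransferScenario) -> SyntheticDataset:
    """Build the full dataset (genomes, features, proteins, hits, tree, truth)."""
    sc = scenario
    if sc.gene_length > sc.genome_length:
        raise ValueError("gene longer than genome")
    recipient = generate_genome(sc.genome_length, sc.recipient_gc,
                                np.random.default_rng((sc.seed, 0)).integers(2**31),
                                seq_id="recipient_genome")
    donor = generate_genome(sc.genome_length, sc.donor_gc,
                            np.random.default_rng((sc.seed, 1)).integers(2**31),
                            seq_id="donor_genome")
    rng = np.random.default_rng((sc.seed, 3))

    # focal gene: donor-like composition iff a transfer happened
    gene_gc = sc.donor_gc if sc.transfer else sc.recipient_gc
    gene_seq = _random_gene(rng, sc.gene_length, gene_gc, sc.motif_embedded)
    locus = sc.genome_length // 2
    residues = (recipient.residues[:locus - 1] + gene_seq
                + recipient.residues[locus - 1 + sc.gene_length:])
    recipient = SequenceRecord(id=recipient.id, residues=residues, alphabet="nt")

    donor_gene_seq = _random_gene(rng, sc.gene_length, sc.donor_gc, False)
    donor_locus = sc.genome_length // 3
    donor_res = (donor.residues[:donor_locus - 1] + donor_gene_seq
                 + donor.residues[donor_locus - 1 + sc.gene_length:])
    donor = SequenceRecord(id=donor.id, residues=donor_res, alphabet="nt")

    gene = GenomicFeature(
        seq_id=recipient.id, feature_type="gene", start=locus,
        end=locus + sc.gene_length - 1, strand="+",
        attributes={"ID": "query_gene"})
    donor_gene = GenomicFeature(
        seq_id=donor.id, feature_type="gene", start=donor_locus,
        end=donor_locus + sc.gene_length - 1, strand="+",
        attributes={"ID": "donor_gene"})
    features = [gene, donor_gene]

    # MGE features inside and outside the downstream/upstream flanks
    mge_classes = ("plasmid", "prophage", "virus")
    counter = 0
    for k in range(sc.mge_within):
        dist = int(rng.integers(200, max(201, sc.flank - 200)))
        length = int(rng.integers(20, 210))
        start = gene.end + dist
        counter += 1
        features.append(GenomicFeature(
            seq_id=recipient.id, feature_type="mge",
            start=start, end=start + length - 1, strand="+",
            attributes={"element_id": f"{mge_classes[k % 3]}:{10000 + counter}",
                        "element_class": mge_classes[k % 3],
                        "host": "synthetic donor-like host",
                        "gc": f"{sc.donor_gc:.1f}",
                        "evalue": "1e-03", "identity": "96"}))
    for k in range(sc.mge_outside):
        dist = sc.flank + 2000 + 500 * k
        length = int(rng.integers(20, 210))
        start = gene.end + dist
        counter += 1
        features.append(GenomicFeature(
            seq_id=recipient.id, feature_type="mge",
            start=start, end=start + length - 1, strand="+",
            attributes={"element_id": f"{mge_classes[k % 3]}:{20000 + counter}",
                        "element_class": mge_classes[k % 3],
                        "host": "synthetic donor-like host",
                        "gc": f"{sc.donor_gc:.1f}",
                        "evalue": "5e-03", "identity": "90"}))

    # proteins: translated focal gene plus one per remaining tree leaf;
    # internal stops from the composition-exact gene are masked with L
    tree_newick = make_tree(sc)
    query_protein = str(Seq(gene_seq).translate()).replace("*", "L")
    aa_len = sc.gene_length // 3
    proteins = [SequenceRecord(id="query_gene", residues=query_protein,
                               alphabet="aa")]
    leaf_names = _leaf_names(tree_newick)
    for name in leaf_names:
        if name != "query_gene":
            proteins.append(SequenceRecord(
                id=name, residues=_random_protein(rng, aa_len), alphabet="aa"))

    # homology table: donor orthologue close, same-lineage hit distant —
    # or the reverse when no transfer occurred
    if sc.transfer:
        donor_ident = float(rng.uniform(80, 100))
        recip_ident = float(rng.uniform(29, 38))
    else:
        donor_ident = float(rng.uniform(29, 38))
        recip_ident = float(rng.uniform(90, 100))
    model = sc.evalue_model
    donor_e = model.evalue(donor_ident, sc.gene_length)
    recip_e = model.evalue(recip_ident, sc.gene_length)
    homology = [
        HomologyHit(query_id="query_gene", subject_id="donor_pap",
                    percent_identity=round(donor_ident, 1),
                    alignment_length=aa_len, evalue=donor_e,
                    bit_score=model.s_match * aa_len * donor_ident / 100,
                    query_coverage=100.0),
        HomologyHit(query_id="query_gene", subject_id="recipient_tnt",
                    percent_identity=round(recip_ident, 1),
                    alignment_length=int(aa_len * 0.5), evalue=recip_e,
                    bit_score=model.s_match * aa_len * recip_ident / 200,
                    query_coverage=50.0),
    ]

    from .alien_index import alien_index  # cycle-free: pure function
    expected_ai = alien_index(recip_e, donor_e)
    truth = {
        "transfer": sc.transfer,
        "donor_leaf": "donor_pap",
        "query_leaf": "query_gene",
        "gene_locus": [gene.start, gene.end],
        "expected": {
            "ai_positive": expected_ai > 30,
            "gc_verdict": ("donor_consistent" if sc.transfer
                           else "host_consistent"),
            "congruent_with_donor": sc.transfer,
            "verdict": "hgt_supported" if sc.transfer else "no_support",
            "mge_within_flank": sc.mge_within,
        },
    }
    return SyntheticDataset(scenario=sc, genomes=[recipient, donor],
                            features=features, proteins=proteins,
                            homology=homology, tree_newick=tree_newick,
                            truth=truth)


def _leaf_names(newick: str) -> list[str]:
    from .phylo_congruence import parse_newick
    return parse_newick(newick).leaf_labels
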