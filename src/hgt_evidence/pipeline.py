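"""Orchestration: run the five evidence stages and aggregate a verdict.

Each focal gene gets an EvidenceRow combining the motif scan, alien index,
G+C affinity, tree congruence and MGE proximity stages. The aggregation
rule is explicit and configurable:

    hgt_supported  iff AI category is very_likely_hgt
                   and (G+C sides with the donor or the tree is congruent)
    no_support     iff AI category is no_hgt_signal
    ambiguous      otherwise
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import alien_index as ai_mod
from . import gc_profile, mge_proximity, phylo_congruence, signature_scan
from .io_formats import (GenomicFeature, read_blast6, read_fasta, read_gff3,
                         write_report_json, write_report_tsv)
from .mge_proximity import MGERecord
from .synthetic_data import SyntheticDataset

logger = logging.getLogger("hgt_evidence")

HGT_SUPPORTED = "hgt_supported"
AMBIGUOUS = "ambiguous"
NO_SUPPORT = "no_support"


@dataclass
class Thresholds:
    ai_very_likely: float = 30.0
    ai_possible: float = 0.0
    identity_rule: bool = False
    collapse_support: float = 700.0
    flank: int = 5000
    max_mismatches: int = 0


@dataclass
class EvidenceRow:
    gene_id: str
    motif_hit: Optional[signature_scan.MotifHit]
    ai: Optional[ai_mod.AlienIndexResult]
    gc: Optional[gc_profile.GCAffinity]
    congruence: Optional[phylo_congruence.CongruenceResult]
    mge_within_flank: Optional[int]
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = _verdict(self.ai, self.gc, self.congruence)

    def as_report_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "motif_start": self.motif_hit.start if self.motif_hit else "",
            "motif_window": self.motif_hit.window if self.motif_hit else "",
            "motif_mismatches": (self.motif_hit.mismatches
                                 if self.motif_hit else ""),
            "alien_index": f"{self.ai.ai:.1f}" if self.ai else "",
            "ai_category": self.ai.category if self.ai else "",
            "gene_gc": f"{self.gc.gene_gc:.1f}" if self.gc else "",
            "host_gc": f"{self.gc.host_genome_gc:.1f}" if self.gc else "",
            "donor_gc": f"{self.gc.donor_gene_gc:.1f}" if self.gc else "",
            "gc_verdict": self.gc.verdict if self.gc else "",
            "nearest_leaf": (self.congruence.nearest_leaf
                             if self.congruence else ""),
            "congruent": (str(self.congruence.congruent).lower()
                          if self.congruence else ""),
            "mge_within_flank": (self.mge_within_flank
                                 if self.mge_within_flank is not None else ""),
            "verdict": self.verdict,
        }


def _verdict(ai, gc, congruence) -> str:
    if ai is None:
        return AMBIGUOUS
    if ai.category == ai_mod.NO_HGT_SIGNAL:
        return NO_SUPPORT
    corroborated = (
        (gc is not None and gc.verdict == gc_profile.DONOR_CONSISTENT)
        or (congruence is not None and congruence.congruent)
    )
    if ai.category == ai_mod.VERY_LIKELY_HGT and corroborated:
        return HGT_SUPPORTED
    return AMBIGUOUS


def analyze_dataset(dataset: SyntheticDataset,
                    thresholds: Optional[Thresholds] = None) -> EvidenceRow:
    """Run every stage on an in-memory synthetic dataset (no file I/O)."""
    th = thresholds or Thresholds()
    sc = dataset.scenario
    genomes = {g.id: g for g in dataset.genomes}
    gene = next(f for f in dataset.features
                if f.attributes.get("ID") == "query_gene")
    donor_gene = next(f for f in dataset.features
                      if f.attributes.get("ID") == "donor_gene")
    mges = [f for f in dataset.features if f.feature_type == "mge"]
    proteins = {p.id: p for p in dataset.proteins}
    return analyze_gene(
        gene_id="query_gene",
        query_protein=proteins.get("query_gene"),
        hits=_grouped_hits(dataset.homology, {"donor_pap"}, {"recipient_tnt"}),
        host_genome=genomes[gene.seq_id],
        gene_feature=gene,
        donor_genome=genomes[donor_gene.seq_id],
        donor_gene_feature=donor_gene,
        tree_newick=dataset.tree_newick,
        query_leaf="query_gene",
        mge_features=mges,
        thresholds=th,
    )


def _grouped_hits(hits, donor_subjects, recipient_subjects):
    for h in hits:
        if h.subject_id in donor_subjects:
            h.subject_group = "donor"
        elif h.subject_id in recipient_subjects:
            h.subject_group = "recipient"
        else:
            h.subject_group = "other"
    return hits


def analyze_gene(gene_id: str, query_protein, hits, host_genome, gene_feature,
                 donor_genome=None, donor_gene_feature=None,
                 tree_newick: Optional[str] = None,
                 query_leaf: Optional[str] = None,
                 mge_features: Optional[list] = None,
                 thresholds: Optional[Thresholds] = None,
                 pattern_text: str = signature_scan.PAP_CONSENSUS,
                 ) -> EvidenceRow:
    """Combine all available evidence stages for one focal gene.

    Optional stages (tree, donor genome, MGEs) are skipped when their
    inputs are absent and recorded as absent in the row.
    """
    th = thresholds or Thresholds()

    motif_hit = None
    if query_protein is not None:
        pattern = signature_scan.parse_pattern(pattern_text)
        if len(query_protein.residues) >= len(pattern):
            motif_hit = signature_scan.best_window(query_protein, pattern)

    pair = ai_mod.best_hits([h for h in hits if h.query_id == gene_id])
    ai_result = ai_mod.evaluate(pair, identity_rule_enabled=th.identity_rule,
                                very_likely_threshold=th.ai_very_likely)

    gc_aff = None
    if donor_genome is not None and donor_gene_feature is not None:
        gene_gc = gc_profile.gene_gc(host_genome, gene_feature).mol_percent
        host_gc = gc_profile.gc_content(host_genome).mol_percent
        donor_gc = gc_profile.gene_gc(donor_genome,
                                      donor_gene_feature).mol_percent
        gc_aff = gc_profile.gc_affinity(gene_gc, host_gc, donor_gc)

    congr = None
    if tree_newick and query_leaf and pair.donor_best is not None:
        tree = phylo_congruence.parse_newick(tree_newick)
        tree = phylo_congruence.collapse_low_support(
            tree, th.collapse_support, redistribute=True)
        congr = phylo_congruence.congruence_check(
            tree, query_leaf, pair.donor_best.subject_id)

    mge_count = None
    if mge_features is not None:
        genome_gc = gc_profile.gc_content(host_genome).mol_percent
        records = [
            MGERecord(
                element_id=f.attributes.get("element_id", "element"),
                element_class=f.attributes.get("element_class", "other"),
                host=f.attributes.get("host", ""),
                match_length=f.length,
                evalue=float(f.attributes.get("evalue", 1.0)),
                percent_identity=float(f.attributes.get("identity", 0.0)),
                location=f,
                gc_percent=(float(f.attributes["gc"])
                            if "gc" in f.attributes else None),
            )
            for f in mge_features if f.seq_id == gene_feature.seq_id
        ]
        rows = mge_proximity.proximity_report(
            gene_feature, records, genome_gc=genome_gc, flank=th.flank)
        mge_count = len(rows)

    return EvidenceRow(gene_id=gene_id, motif_hit=motif_hit, ai=ai_result,
                       gc=gc_aff, congruence=congr,
                       mge_within_flank=mge_count)


# ---------------------------------------------------------------------------
# file-driven run

def load_config(path) -> dict:
    """Read the INI run configuration ([inputs], [thresholds], [stages])."""
    import configparser

    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(f"config file {path!r} not found")
    cfg = {section: dict(cp[section]) for section in cp.sections()}
    cfg.setdefault("inputs", {})
    cfg.setdefault("thresholds", {})
    cfg.setdefault("stages", {})
    return cfg


def _thresholds_from_config(cfg: dict) -> Thresholds:
    t = cfg.get("thresholds", {})
    return Thresholds(
        ai_very_likely=float(t.get("ai_very_likely", 30)),
        ai_possible=float(t.get("ai_possible", 0)),
        identity_rule=str(t.get("identity_rule", "false")).lower() == "true",
        collapse_support=float(t.get("collapse_support", 700)),
        flank=int(t.get("flank", 5000)),
        max_mismatches=int(t.get("max_mismatches", 0)),
    )


def run_pipeline(config, out_dir=None) -> list[EvidenceRow]:
    """Run all configured stages from files named in the configuration.

    ``config`` is a path to an INI file or an equivalent nested dict. All
    referenced files are checked before any stage runs. Writes report.tsv
    and report.json into ``out_dir`` when given. Finding no HGT is a normal
    result, not an error.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    inputs = cfg.get("inputs", {})
    stages = cfg.get("stages", {})
    th = _thresholds_from_config(cfg)

    def on(stage: str) -> bool:
        return str(stages.get(stage, "true")).lower() != "false"

    file_keys = [k for k in ("genomes", "proteins", "features", "hits", "tree")
                 if inputs.get(k)]
    missing = [inputs[k] for k in file_keys if not Path(inputs[k]).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    genomes = {}
    if inputs.get("genomes"):
        with open(inputs["genomes"]) as fh:
            genomes = {g.id: g for g in read_fasta(fh, alphabet="nt")}
    proteins = {}
    if inputs.get("proteins"):
        with open(inputs["proteins"]) as fh:
            proteins = {p.id: p for p in read_fasta(fh, alphabet="aa")}
    features = []
    if inputs.get("features"):
        with open(inputs["features"]) as fh:
            features = read_gff3(fh)
    hits = []
    if inputs.get("hits"):
        with open(inputs["hits"]) as fh:
            hits = read_blast6(fh)
    tree_newick = (Path(inputs["tree"]).read_text()
                   if inputs.get("tree") and on("congruence") else None)

    donor_subjects = {s.strip() for s in inputs.get("donor_subjects", "").split(",") if s.strip()}
    recipient_subjects = {s.strip() for s in inputs.get("recipient_subjects", "").split(",") if s.strip()}
    _grouped_hits(hits, donor_subjects, recipient_subjects)

    gene_ids = [g.strip() for g in inputs.get("query_genes", "").split(",")
                if g.strip()]
    by_id = {f.attributes.get("ID"): f for f in features}
    unknown = [g for g in gene_ids if g not in by_id]
    if unknown:
        raise ValueError(f"query genes not present in features: {unknown}")
    donor_gene_id = inputs.get("donor_gene")
    donor_gene_feature = by_id.get(donor_gene_id) if donor_gene_id else None
    mges = ([f for f in features if f.feature_type == "mge"]
            if on("mge") else None)

    rows = []
    for gid in gene_ids:
        gene_feature = by_id[gid]
        host = genomes.get(gene_feature.seq_id)
        if host is None:
            raise ValueError(
                f"gene {gid}: genome {gene_feature.seq_id!r} not in FASTA")
        donor_genome = (genomes.get(donor_gene_feature.seq_id)
                        if donor_gene_feature is not None and on("gc")
                        else None)
        logger.info("analyzing gene %s", gid)
        rows.append(analyze_gene(
            gene_id=gid,
            query_protein=proteins.get(gid) if on("motif") else None,
            hits=hits,
            host_genome=host,
            gene_feature=gene_feature,
            donor_genome=donor_genome,
            donor_gene_feature=donor_gene_feature if on("gc") else None,
            tree_newick=tree_newick,
            query_leaf=gid,
            mge_features=mges,
            thresholds=th,
        ))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report = [r.as_report_dict() for r in rows]
        with open(out / "report.tsv", "w") as fh:
            write_report_tsv(report, fh)
        with open(out / "report.json", "w") as fh:
            write_report_json(report, fh)
        with open(out / "summary.json", "w") as fh:
            json.dump(summarize(rows), fh, indent=2)
            fh.write("\n")
    return rows


def summarize(rows: list[EvidenceRow]) -> dict:
    """Run-level counts per verdict / AI category, plus MGE-positive genes."""
    verdicts = {HGT_SUPPORTED: 0, AMBIGUOUS: 0, NO_SUPPORT: 0}
    categories: dict[str, int] = {}
    mge_positive = 0
    for r in rows:
        verdicts[r.verdict] += 1
        if r.ai is not None:
            categories[r.ai.category] = categories.get(r.ai.category, 0) + 1
        if r.mge_within_flank:
            mge_positive += 1
    return {
        "genes": len(rows),
        "verdicts": verdicts,
        "ai_categories": dict(sorted(categories.items())),
        "mge_positive": mge_positive,
    }
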