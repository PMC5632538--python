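"""End-to-end orchestration: load study inputs, run every stage, write outputs.

The file formats emitted by :mod:`cernet.simulate` (or prepared by hand in
the same layout) are the interface: GTF annotation, FASTA sequences, a
counts TSV with a group map, a feature-class map, and a QTL BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diffexpr, io as cio, lncrna, network as net_mod, targets as tgt
from .core import Config, ExpressionMatrix, GenomicInterval, SequenceRecord, TranscriptRecord, default_contrasts


@dataclass
class StudyInputs:
    records: list[TranscriptRecord]
    counts: ExpressionMatrix
    feature_class: dict[str, str]
    known_ids: dict[str, str]
    mirnas: list[SequenceRecord]
    utrs: list[SequenceRecord]
    lnc_seqs: list[SequenceRecord]
    candidate_seqs: list[SequenceRecord]
    qtl: GenomicInterval


@dataclass
class AnalysisResult:
    filter_reports: list = field(default_factory=list)
    survivors: list = field(default_factory=list)
    de_results: dict = field(default_factory=dict)
    de_union: set = field(default_factory=set)
    de_by_contrast: dict = field(default_factory=dict)
    size_factors: dict = field(default_factory=dict)
    newick: str = ""
    trans_edges: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    mir_mrna_candidates: list = field(default_factory=list)
    lnc_roles: dict = field(default_factory=dict)
    lnc_mir_edges: list = field(default_factory=list)
    network: net_mod.NetworkGraph = field(default_factory=net_mod.NetworkGraph)
    bridges: list = field(default_factory=list)
    qtl_set: net_mod.QTLCandidateSet | None = None


def load_inputs(in_dir: str | Path) -> StudyInputs:
    d = Path(in_dir)
    records = cio.read_annotation(d / "annotation.gtf")
    groups = cio.read_groups(d / "groups.tsv")
    counts = cio.read_counts(d / "counts.tsv", groups)
    feature_class = {}
    with open(d / "feature_class.tsv") as fh:
        for line in fh:
            fid, cls = line.strip().split("\t")
            feature_class[fid] = cls
    known_ids = {}
    known_path = d / "known_ids.tsv"
    if known_path.exists():
        with open(known_path) as fh:
            for line in fh:
                fid, biotype = line.strip().split("\t")
                known_ids[fid] = biotype
    def fasta(name):
        p = d / name
        return cio.read_fasta(p) if p.exists() else []
    return StudyInputs(
        records=records,
        counts=counts,
        feature_class=feature_class,
        known_ids=known_ids,
        mirnas=cio.read_fasta(d / "mirna.fa", alphabet="RNA") if (d / "mirna.fa").exists() else [],
        utrs=fasta("utr.fa"),
        lnc_seqs=fasta("lncrna.fa"),
        candidate_seqs=fasta("candidates.fa"),
        qtl=cio.read_bed_interval(d / "qtl.bed"),
    )


def analyze(inputs: StudyInputs, cfg: Config, scan_all: bool = False) -> AnalysisResult:
    """Run the full analysis on in-memory inputs."""
    res = AnalysisResult()
    contrasts = default_contrasts()

    # 1. biotype classification + lncRNA candidate filter
    records = lncrna.classify_transcripts(inputs.records, inputs.known_ids)
    cand_seqs = {s.id: s for s in inputs.candidate_seqs}
    res.survivors, res.filter_reports = lncrna.filter_candidates(
        records, cfg, sequences=cand_seqs
    )

    # 2. differential expression per class and contrast
    res.de_results = diffexpr.run_de(inputs.counts, contrasts, inputs.feature_class, cfg)
    res.de_by_contrast = diffexpr.de_feature_sets(res.de_results)
    res.de_union = set().union(*res.de_by_contrast.values()) if res.de_by_contrast else set()
    for cls in sorted(set(inputs.feature_class.values())):
        ids = [f for f in inputs.counts.feature_ids if inputs.feature_class.get(f) == cls]
        if ids:
            res.size_factors[cls] = diffexpr.size_factors(inputs.counts.subset_features(ids))

    # 3. sample clustering on log10 FPKM
    lengths = {r.transcript_id: r.length() for r in records}
    lengths = {f: lengths.get(f, 1000) for f in inputs.counts.feature_ids}
    transformed = diffexpr.transform_expression(inputs.counts, lengths, "FPKM")
    res.newick, _, _ = diffexpr.cluster_samples(transformed)

    # correlations are computed on the log-transformed expression: raw-count
    # Pearson r cannot reach the thresholds for anti-regulated pairs whose
    # group means move exponentially in opposite directions
    def class_expr(cls: str) -> ExpressionMatrix:
        ids = [f for f in transformed.feature_ids if inputs.feature_class.get(f) == cls]
        return transformed.subset_features(ids)

    lnc_expr = class_expr("lncRNA")
    mrna_expr = class_expr("mRNA")
    mir_expr = class_expr("miRNA")

    # 4. lncRNA trans-target inference (|r| >= r_trans)
    if lnc_expr.shape[0] and mrna_expr.shape[0]:
        res.trans_edges, _ = tgt.trans_targets(lnc_expr, mrna_expr, cfg)

    # 5. miRNA site scanning (restricted to DE features unless scan_all)
    de = res.de_union
    scan_mirnas = [m for m in inputs.mirnas if scan_all or m.id in de]
    utr_by_id = {u.id: u for u in inputs.utrs}
    regions = [
        tgt.extract_scan_region(r, utr_by_id, None, cfg)
        for r in records
        if inputs.feature_class.get(r.transcript_id) == "mRNA"
        and (scan_all or r.transcript_id in de)
        and r.transcript_id in utr_by_id
    ]
    regions = [r for r in regions if r is not None]
    lnc_regions = [s for s in inputs.lnc_seqs if scan_all or s.id in de]
    sites_mrna = tgt.scan_many(scan_mirnas, regions, cfg)
    sites_lnc = tgt.scan_many(scan_mirnas, lnc_regions, cfg)
    res.sites = sites_mrna + sites_lnc

    # 6. miRNA-mRNA candidates: site evidence + correlation
    mir_pos = {f: i for i, f in enumerate(mir_expr.feature_ids)}
    mrna_pos = {f: i for i, f in enumerate(mrna_expr.feature_ids)}
    r_mat = (
        tgt.correlation_matrix(mir_expr, mrna_expr)
        if mir_expr.shape[0] and mrna_expr.shape[0]
        else np.zeros((0, 0))
    )
    seen = set()
    for s in sites_mrna:
        key = (s.mirna_id, s.target_id)
        if key in seen or s.mirna_id not in mir_pos or s.target_id not in mrna_pos:
            continue
        seen.add(key)
        r = float(r_mat[mir_pos[s.mirna_id], mrna_pos[s.target_id]])
        if not np.isnan(r):
            res.mir_mrna_candidates.append((s.mirna_id, s.target_id, r, True))
    res.mir_mrna_candidates.sort()

    # 7. lncRNA role classification and network assembly
    admitted = [
        tgt.CorrelationEdge(mir, mrna, r, len(mir_expr.sample_ids), "mir_mrna")
        for mir, mrna, r, site in res.mir_mrna_candidates
        if site and abs(r) > cfg.r_pair and mir in de and mrna in de
    ]
    if sites_lnc and lnc_expr.shape[0] and mir_expr.shape[0]:
        res.lnc_roles, res.lnc_mir_edges = net_mod.classify_lncrna_roles(
            sites_lnc, lnc_expr, mir_expr, mrna_expr, admitted, cfg
        )
    res.network = net_mod.build_network(
        de, res.lnc_roles, res.lnc_mir_edges, res.mir_mrna_candidates, cfg
    )
    res.bridges = net_mod.find_bridges(res.network)

    # 8. QTL co-localization of DE features
    feature_records = [r for r in records if r.transcript_id in inputs.feature_class]
    res.qtl_set = net_mod.qtl_colocalize(feature_records, de, inputs.qtl, cfg)
    return res


def write_results(res: AnalysisResult, out_dir: str | Path, header: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lncrna.write_filter_report(res.filter_reports, out / "filter_report.tsv", header)
    for cname, per_class in sorted(res.de_results.items()):
        for cls, results in sorted(per_class.items()):
            path = out / f"de_{cname}_{cls}.tsv"
            with open(path, "w") as fh:
                if header:
                    fh.write(header)
                fh.write("feature\tbase_mean\tlog2fc\tp\tq\tdirection\n")
                for r in sorted(results, key=lambda r: r.feature_id):
                    fh.write(
                        f"{r.feature_id}\t{r.base_mean:.4f}\t{r.log2fc:.4f}"
                        f"\t{r.p:.6g}\t{r.q:.6g}\t{r.direction}\n"
                    )
    (out / "dendrogram.nwk").write_text(res.newick + "\n")
    if res.size_factors:
        with open(out / "size_factors.tsv", "w") as fh:
            if header:
                fh.write(header)
            fh.write("class\tsample\tfactor\n")
            for cls, factors in sorted(res.size_factors.items()):
                for sample, value in factors.items():
                    fh.write(f"{cls}\t{sample}\t{value:.6f}\n")
    tgt.write_edges(res.trans_edges, out / "trans_targets.tsv", header)
    tgt.write_sites(res.sites, out / "mirna_sites.tsv", header)
    cio.write_network_sif(
        res.network, out / "network.sif", out / "node_attributes.tsv", header
    )
    with open(out / "bridges.tsv", "w") as fh:
        if header:
            fh.write(header)
        fh.write("mrna\tmirna_degree\n")
        for mrna, deg in res.bridges:
            fh.write(f"{mrna}\t{deg}\n")
    if res.qtl_set is not None:
        with open(out / "qtl_candidates.tsv", "w") as fh:
            if header:
                fh.write(header)
            fh.write("feature\tclass\n")
            for fid in sorted(res.qtl_set.genes):
                fh.write(f"{fid}\tgene\n")
            for fid in sorted(res.qtl_set.lncrnas):
                fh.write(f"{fid}\tlncRNA\n")
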