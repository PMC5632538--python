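"""Readers and writers for the pipeline's text formats.

GTF is 1-based inclusive on disk and converted to the internal 0-based
half-open convention at this boundary.  BED is native.  Every writer can
prepend a deterministic provenance header (version, seed, config hash).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from . import __version__
from .core import (
    Config,
    ExpressionMatrix,
    GenomicInterval,
    SequenceRecord,
    TranscriptRecord,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

#: attribute keys that map onto TranscriptRecord fields rather than attrs
_RESERVED_ATTRS = ("transcript_id", "gene_id", "cov", "samples", "biotype")


def provenance_header(seed: int | None, config: Config | None) -> str:
    """Comment header for output files: version, seed, config hash."""
    parts = [f"# cernet {__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config is not None:
        parts.append(f"# config={config.hash()}")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[TranscriptRecord]:
    """Parse exon features of a GTF file into transcript records.

    Exon lines are grouped by ``transcript_id``; coordinates come back
    0-based half-open.  Recognized attributes: ``gene_id``, ``cov`` (mean
    depth), ``samples`` (comma list), ``biotype``.  Anything else is kept in
    the record's pass-through ``attrs`` map.
    """
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates")
            attrs = dict(_ATTR_RE.findall(attr_s))
            tid = attrs.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}: line {lineno}: exon without transcript_id")
            exon = GenomicInterval(chrom, start_i - 1, end_i, strand)
            if tid not in groups:
                groups[tid] = {"exons": [], "attrs": attrs}
                order.append(tid)
            groups[tid]["exons"].append(exon)

    records = []
    for tid in order:
        info = groups[tid]
        exons = sorted(info["exons"], key=lambda e: e.start)
        attrs = info["attrs"]
        interval = GenomicInterval(
            exons[0].chrom, exons[0].start, max(e.end for e in exons), exons[0].strand
        )
        samples = attrs.get("samples", "")
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=attrs.get("gene_id", tid),
                interval=interval,
                exons=exons,
                coverage=float(attrs.get("cov", 0.0)),
                present_in_samples=set(filter(None, samples.split(","))),
                biotype=attrs.get("biotype", "novel_candidate"),
                attrs={k: v for k, v in attrs.items() if k not in _RESERVED_ATTRS},
            )
        )
    return records


def write_annotation(
    records: Iterable[TranscriptRecord],
    path: str | Path,
    header: str = "",
) -> None:
    """Write transcript records as GTF exon lines (inverse of read_annotation)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for rec in records:
            attrs = [
                f'transcript_id "{rec.transcript_id}"',
                f'gene_id "{rec.gene_id}"',
                f'cov "{rec.coverage:g}"',
                f'samples "{",".join(sorted(rec.present_in_samples))}"',
                f'biotype "{rec.biotype}"',
            ]
            attrs += [f'{k} "{v}"' for k, v in sorted(rec.attrs.items())]
            attr_s = "; ".join(attrs) + ";"
            for exon in rec.exons:
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "cernet",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attr_s,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Counts / expression TSV
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path, groups: Mapping[str, str], kind: str = "counts"
) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column feature ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate feature ids: {dups[:5]}")
    arr = df.to_numpy()
    try:
        arr.astype(float)
    except (ValueError, TypeError):
        raise ValueError(f"{path}: non-numeric cells present")
    return ExpressionMatrix(df, groups, kind=kind)


def write_counts(mat: ExpressionMatrix, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        mat.values.to_csv(fh, sep="\t", index_label="feature_id", lineterminator="\n")


def read_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV sample_id<TAB>group."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sample, group = line.split("\t")[:2]
            out[sample] = group
    return out


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "DNA") -> list[SequenceRecord]:
    return [
        SequenceRecord(id=r.id, seq=str(r.seq), alphabet=alphabet)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed_interval(path: str | Path) -> GenomicInterval:
    """Read the first interval of a BED file (0-based half-open, native)."""
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            return GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
    raise ValueError(f"{path}: no intervals found")


def write_bed_interval(
    interval: GenomicInterval, path: str | Path, name: str = "region"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"{interval.chrom}\t{interval.start}\t{interval.end}\t{name}\n")


# ---------------------------------------------------------------------------
# SIF network export (see network module for graph type)
# ---------------------------------------------------------------------------

def write_network_sif(net, path: str | Path, attr_path: str | Path | None = None,
                      header: str = "") -> None:
    """Write edges as SIF lines ``source <relation> target``, sorted.

    Ordering is lexicographic over (source, relation, target), so output is
    byte-identical across runs.  If *attr_path* is given, a node-attribute
    TSV (id, node_type, role) is written alongside.
    """
    lines = sorted(
        f"{a}\t{etype}\t{b}" for a, b, etype in net.edge_triples()
    )
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for line in lines:
            fh.write(line + "\n")
    if attr_path is not None:
        with open(attr_path, "w") as fh:
            if header:
                fh.write(header)
            fh.write("id\tnode_type\trole\n")
            for nid, ntype, role in sorted(net.node_triples()):
                fh.write(f"{nid}\t{ntype}\t{role}\n")


# ---------------------------------------------------------------------------
# Config file
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None, warn=None) -> Config:
    """Load a flat key=value config file; missing path -> all defaults."""
    if path is None:
        return Config()
    text = Path(path).read_text()
    return Config.from_text(text, warn=warn)


def save_config(cfg: Config, path: str | Path) -> None:
    Path(path).write_text(cfg.to_text())
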