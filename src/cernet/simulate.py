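"""Synthetic-study generator: annotation, sequences, grouped NB counts,
and a ground-truth table for recovery testing.

The design mirrors a 4-group (V/Q/C/R) x 3-replicate study.  Differential
expression is planted along the contrast chain V->Q->C->R so each contrast
owns a truth set.  ceRNA triads couple group means: the miRNA follows a
shared group-level pattern and its partners follow it with sign +/-1
depending on the planted role, so strong cross-feature correlations arise
from group means (which is all an n=12 Pearson threshold can detect).

Role conventions (so the downstream classifier is separable):
  * target triad: mRNA and lncRNA both move opposite to the miRNA
    (lncRNA-miRNA correlation strongly negative).
  * decoy triad: mRNA and lncRNA both move with the miRNA (lncRNA-miRNA
    correlation positive; lncRNA-mRNA strongly positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    Config,
    ExpressionMatrix,
    GenomicInterval,
    GROUPS,
    SequenceRecord,
    TranscriptRecord,
    parse_interval,
)
from . import io as cio

DNA = "ACGT"
RNA_BASES = "ACGU"
_REVCOMP_RNA_TO_DNA = str.maketrans("ACGU", "TGCA")

#: one deliberately non-compliant novel record per filter criterion, plus
#: one compliant record; used by the filter-cascade tests end to end.
FILTER_FIXTURE_IDS = (
    "novel_ok",
    "novel_len",
    "novel_exon",
    "novel_cov",
    "novel_recur",
    "novel_known",
    "novel_coding",
)


@dataclass
class SimulationParams:
    n_mrna: int = 3000
    n_lncrna: int = 400
    n_mirna: int = 100
    n_chroms: int = 16
    chrom_length: int = 15_000_000  # every chromosome; chr11 must hold the QTL
    n_reps: int = 3
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    libsize_log_sd: float = 0.2
    de_fraction: float = 0.10
    lfc_low: float = 1.0
    lfc_high: float = 3.0
    n_triads: int = 50
    coupling_strength: float = 0.9
    triad_lfc_low: float = 2.5
    triad_lfc_high: float = 3.0
    sites_per_target: tuple[int, int] = (1, 3)
    utr_len: tuple[int, int] = (200, 2000)
    mirna_len: tuple[int, int] = (20, 24)
    qtl_fraction: float = 0.05
    qtl_interval: str = "chr11:8900000-12200000"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_chroms", "n_triads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        for name in ("de_fraction", "qtl_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_triads > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValueError("n_triads exceeds available features of some class")
        qtl = parse_interval(self.qtl_interval)
        if self.chrom_length < qtl.end:
            raise ValueError(
                f"chromosomes of length {self.chrom_length} cannot hold the "
                f"QTL window ending at {qtl.end}"
            )

    @property
    def qtl(self) -> GenomicInterval:
        return parse_interval(self.qtl_interval)

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}{i + 1}" for g in GROUPS for i in range(self.n_reps)]

    @property
    def sample_group(self) -> dict[str, str]:
        return {s: s[0] for s in self.sample_ids}


@dataclass
class TruthTable:
    """Everything the generator planted, for recovery tests."""

    de_sets: dict = field(default_factory=dict)  # contrast -> class -> [(id, sign)]
    triads: list = field(default_factory=list)  # (lnc, mir, mrna, role)
    planted_sites: list = field(default_factory=list)  # (mir, target, pos)
    qtl_members: list = field(default_factory=list)
    group_means: dict = field(default_factory=dict)  # id -> {group: mean}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = json.loads(Path(path).read_text())
        return cls(
            de_sets=d["de_sets"],
            triads=[tuple(t) for t in d["triads"]],
            planted_sites=[tuple(s) for s in d["planted_sites"]],
            qtl_members=list(d["qtl_members"]),
            group_means=d["group_means"],
        )

    def triad_edges(self) -> set[tuple[str, str, str]]:
        """Planted network edges as (a, b, edge_type) with a < b."""
        out = set()
        for lnc, mir, mrna, role in self.triads:
            out.add((min(lnc, mir), max(lnc, mir), f"lnc_mir_{role}"))
            out.add((min(mir, mrna), max(mir, mrna), "mir_mrna"))
        return out


@dataclass
class SimulatedStudy:
    params: SimulationParams
    records: list[TranscriptRecord]
    qtl: GenomicInterval
    mirnas: list[SequenceRecord]
    utrs: list[SequenceRecord]
    lnc_seqs: list[SequenceRecord]
    candidate_seqs: list[SequenceRecord]
    counts: ExpressionMatrix
    feature_class: dict[str, str]
    known_ids: dict[str, str]
    truth: TruthTable


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_exons(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    span: int,
    n_exons: int,
    min_exon: int,
    strand: str,
) -> list[GenomicInterval]:
    """n non-overlapping exons inside [start, start+span), each >= min_exon."""
    seg = span // n_exons
    exons = []
    for k in range(n_exons):
        lo = start + k * seg
        max_len = min(seg, span - k * seg)
        length = int(rng.integers(min_exon, max(min_exon + 1, max_len // 2 + 1)))
        length = min(length, max_len)
        offset = int(rng.integers(0, max(1, max_len - length + 1)))
        exons.append(GenomicInterval(chrom, lo + offset, lo + offset + length, strand))
    return exons


def _place_span(
    rng: np.random.Generator,
    params: SimulationParams,
    span: int,
    inside_qtl: bool,
) -> tuple[str, int]:
    qtl = params.qtl
    if inside_qtl:
        start = int(rng.integers(qtl.start, qtl.end - span))
        return qtl.chrom, start
    while True:
        chrom = f"chr{int(rng.integers(1, params.n_chroms + 1))}"
        start = int(rng.integers(0, params.chrom_length - span))
        if chrom == qtl.chrom and qtl.contains(
            GenomicInterval(chrom, start, start + span)
        ):
            continue
        return chrom, start


def simulate_annotation(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[list[TranscriptRecord], GenomicInterval, dict[str, str]]:
    """Transcript records for all feature classes plus the QTL interval.

    Returns (records, qtl_interval, feature_class map).  A qtl_fraction of
    each class is placed fully inside the QTL window; everything else is
    rejection-sampled to avoid full containment.  The filter-cascade
    fixture records (one violator per criterion + one compliant) are
    appended as novel candidates.
    """
    records: list[TranscriptRecord] = []
    feature_class: dict[str, str] = {}
    samples = set(params.sample_ids)

    specs = [
        ("mRNA", params.n_mrna, "known_mRNA", (2000, 10000), (2, 8), 100),
        ("lncRNA", params.n_lncrna, "known_lncRNA", (1000, 5000), (2, 4), 150),
        ("miRNA", params.n_mirna, "known_other", (80, 120), (1, 1), 80),
    ]
    for cls, n, biotype, span_rng, exon_rng, min_exon in specs:
        n_inside = int(round(params.qtl_fraction * n))
        for k in range(n):
            fid = f"{cls.lower()[:3]}_{k + 1:04d}" if cls != "miRNA" else f"mir_{k + 1:04d}"
            span = int(rng.integers(span_rng[0], span_rng[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = _place_span(rng, params, span, inside_qtl=k < n_inside)
            n_exons = int(rng.integers(exon_rng[0], exon_rng[1] + 1))
            exons = _make_exons(rng, chrom, start, span, n_exons, min_exon, strand)
            interval = GenomicInterval(chrom, start, start + span, strand)
            records.append(
                TranscriptRecord(
                    transcript_id=fid,
                    gene_id=fid,
                    interval=interval,
                    exons=exons,
                    coverage=float(rng.uniform(5, 50)),
                    present_in_samples=set(samples),
                    biotype=biotype,
                )
            )
            feature_class[fid] = cls
    records.extend(_filter_fixture_records(params, samples))
    return records, params.qtl, feature_class


def _filter_fixture_records(
    params: SimulationParams, samples: set[str]
) -> list[TranscriptRecord]:
    def rec(fid, exon_lens, coverage=10.0, present=None, attrs=None):
        start = 1000
        exons, pos = [], start
        for ln in exon_lens:
            exons.append(GenomicInterval("chr1", pos, pos + ln, "+"))
            pos += ln + 200
        return TranscriptRecord(
            transcript_id=fid,
            gene_id=fid,
            interval=GenomicInterval("chr1", start, pos - 200, "+"),
            exons=exons,
            coverage=coverage,
            present_in_samples=set(samples) if present is None else present,
            biotype="novel_candidate",
            attrs=attrs or {},
        )

    one_sample = {sorted(samples)[0]} if samples else set()
    return [
        rec("novel_ok", [250, 250]),
        rec("novel_len", [75, 75]),  # spliced length 150 < 200
        rec("novel_exon", [500]),  # single exon
        rec("novel_cov", [250, 250], coverage=1.0),
        rec("novel_recur", [250, 250], present=one_sample),
        rec("novel_known", [250, 250], attrs={"known_overlap": "1"}),
        rec("novel_coding", [350, 350]),  # paired with a coding sequence
    ]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, alphabet: str = DNA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _random_seq_no_atg(rng: np.random.Generator, length: int) -> str:
    """Uniform DNA with every ATG occurrence broken (so no ORF exists)."""
    s = list(_random_seq(rng, length))
    text = "".join(s)
    while "ATG" in text:
        i = text.index("ATG")
        s[i + 2] = "C"
        text = "".join(s)
    return text


def simulate_sequences(
    params: SimulationParams,
    records: Sequence[TranscriptRecord],
    feature_class: dict[str, str],
    rng: np.random.Generator,
    triad_mirnas: set[str],
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[SequenceRecord], list[SequenceRecord]]:
    """(mirnas, utrs, lncrna spliced seqs, filter-fixture candidate seqs).

    miRNAs carrying planted sites are drawn at >= 22 nt: with match +5 and
    the 7 seed positions doubled, a perfect duplex scores 5L + 35, which
    only exceeds the 140 retention threshold for L >= 22.
    """
    mirnas, utrs, lnc_seqs = [], [], []
    lo, hi = params.mirna_len
    for recd in records:
        cls = feature_class.get(recd.transcript_id)
        if cls == "miRNA":
            if recd.transcript_id in triad_mirnas:
                length = int(rng.integers(max(lo, 22), hi + 1))
            else:
                length = int(rng.integers(lo, hi + 1))
            mirnas.append(
                SequenceRecord(recd.transcript_id, _random_seq(rng, length, RNA_BASES), "RNA")
            )
        elif cls == "mRNA":
            ulen = int(rng.integers(params.utr_len[0], params.utr_len[1] + 1))
            utrs.append(SequenceRecord(recd.transcript_id, _random_seq(rng, ulen), "DNA"))
        elif cls == "lncRNA":
            length = max(recd.length(), 200)
            lnc_seqs.append(
                SequenceRecord(recd.transcript_id, _random_seq(rng, length), "DNA")
            )
    candidate_seqs = _filter_fixture_seqs(records, rng)
    return mirnas, utrs, lnc_seqs, candidate_seqs


def _filter_fixture_seqs(
    records: Sequence[TranscriptRecord], rng: np.random.Generator
) -> list[SequenceRecord]:
    out = []
    by_id = {r.transcript_id: r for r in records}
    for fid in FILTER_FIXTURE_IDS:
        if fid not in by_id:
            continue
        length = by_id[fid].length()
        if fid == "novel_coding":
            seq = "ATG" + "GCC" * ((length - 6) // 3) + "TAA"
        else:
            seq = _random_seq_no_atg(rng, length)
        out.append(SequenceRecord(fid, seq, "DNA"))
    return out


def plant_sites(
    params: SimulationParams,
    mirnas: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    pairs: Sequence[tuple[str, str, int]],
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], list[tuple[str, str, int]]]:
    """Overwrite each designated target with full reverse complements.

    *pairs* is (mirna_id, target_id, n_copies).  Each copy replaces a
    stretch of the target with the DNA reverse complement of the miRNA at
    a recorded non-overlapping position (a maximal-score site by
    construction).  Raises if a target is too short for its copies.
    """
    mir_by_id = {m.id: m for m in mirnas}
    out = {t.id: t.seq for t in targets}
    planted: list[tuple[str, str, int]] = []
    for mir_id, target_id, copies in pairs:
        mir = mir_by_id[mir_id]
        site = mir.seq.translate(_REVCOMP_RNA_TO_DNA)[::-1]
        L = len(site)
        seq = out[target_id]
        if copies * (L + 1) > len(seq):
            raise ValueError(
                f"{target_id}: length {len(seq)} cannot host {copies} sites of {L} nt"
            )
        taken: list[tuple[int, int]] = []
        for _ in range(copies):
            for _attempt in range(1000):
                pos = int(rng.integers(0, len(seq) - L + 1))
                if all(pos + L <= a or pos >= b for a, b in taken):
                    break
            else:
                raise ValueError(f"{target_id}: cannot place non-overlapping sites")
            taken.append((pos, pos + L))
            seq = seq[:pos] + site + seq[pos + L :]
            planted.append((mir_id, target_id, pos))
        out[target_id] = seq
    return (
        [SequenceRecord(t.id, out[t.id], t.alphabet) for t in targets],
        planted,
    )


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _contrast_chain() -> list[tuple[str, str, str]]:
    return [("Q_V", "Q", "V"), ("C_Q", "C", "Q"), ("R_C", "R", "C")]


def plan_truth(
    params: SimulationParams,
    feature_class: dict[str, str],
    rng: np.random.Generator,
) -> tuple[TruthTable, dict[str, np.ndarray]]:
    """Draw triads, DE sets and true group means (log2 offsets from baseline).

    Returns (truth, offsets) where offsets[fid] is the per-group log2
    shift relative to the feature's baseline mean, ordered as GROUPS.
    """
    by_class: dict[str, list[str]] = {"mRNA": [], "lncRNA": [], "miRNA": []}
    for fid, cls in feature_class.items():
        by_class[cls].append(fid)
    for ids in by_class.values():
        ids.sort()

    truth = TruthTable()
    offsets: dict[str, np.ndarray] = {
        fid: np.zeros(len(GROUPS)) for fid in feature_class
    }

    # --- triads ---------------------------------------------------------
    tri_l = list(rng.choice(by_class["lncRNA"], size=params.n_triads, replace=False)) if params.n_triads else []
    tri_m = list(rng.choice(by_class["miRNA"], size=params.n_triads, replace=False)) if params.n_triads else []
    tri_g = list(rng.choice(by_class["mRNA"], size=params.n_triads, replace=False)) if params.n_triads else []
    c = params.coupling_strength
    for k in range(params.n_triads):
        role = "target" if k % 2 == 0 else "decoy"
        lnc, mir, mrna = str(tri_l[k]), str(tri_m[k]), str(tri_g[k])
        truth.triads.append((lnc, mir, mrna, role))
        # zig-zag group pattern: every contrast sees a |log2FC| in
        # [triad_lfc_low, triad_lfc_high] while the overall dynamic range
        # stays bounded, so low-count saturation cannot wash out the signal
        amp = rng.uniform(params.triad_lfc_low, params.triad_lfc_high) / 2.0
        phase = float(rng.choice([-1.0, 1.0]))
        f = phase * amp * np.array([1.0, -1.0, 1.0, -1.0])  # V, Q, C, R
        f += rng.normal(0.0, 0.1, size=len(GROUPS))
        # the miRNA is the clean driver; partners follow with an idiosyncratic
        # group-level wobble of (1 - coupling) times the shared pattern's sd
        sd_idio = float(np.std(f) * (1 - c))
        direction = {"mir": 1.0, "mrna": -1.0, "lnc": -1.0}
        if role == "decoy":
            direction = {"mir": 1.0, "mrna": 1.0, "lnc": 1.0}
        for member, fid in (("mir", mir), ("mrna", mrna), ("lnc", lnc)):
            idio = (
                rng.normal(0.0, sd_idio, size=len(GROUPS))
                if sd_idio > 0 and member != "mir"
                else np.zeros(len(GROUPS))
            )
            offsets[fid] = direction[member] * f + idio

    triad_ids = {fid for t in truth.triads for fid in t[:3]}

    # --- independent planted DE along the chain -------------------------
    chain = _contrast_chain()
    truth.de_sets = {name: {cls: [] for cls in by_class} for name, _, _ in chain}
    for cls, ids in by_class.items():
        free = [f for f in ids if f not in triad_ids]
        n_de = int(round(params.de_fraction * len(free)))
        for ci, (cname, _t, _r) in enumerate(chain):
            if n_de == 0 or not free:
                continue
            chosen = rng.choice(free, size=min(n_de, len(free)), replace=False)
            for fid in chosen:
                fid = str(fid)
                sign = float(rng.choice([-1.0, 1.0]))
                lfc = float(rng.uniform(params.lfc_low, params.lfc_high))
                # shift treatment group and everything downstream of it
                offsets[fid][ci + 1 :] += sign * lfc
                truth.de_sets[cname][cls].append((fid, int(sign)))

    # triad members are genuinely DE in every contrast; record realized signs
    for cname_i, (cname, _t, _r) in enumerate(chain):
        for lnc, mir, mrna, _role in truth.triads:
            for fid in (lnc, mir, mrna):
                cls = feature_class[fid]
                diff = offsets[fid][cname_i + 1] - offsets[fid][cname_i]
                truth.de_sets[cname][cls].append((fid, 1 if diff > 0 else -1))
    return truth, offsets


def simulate_counts(
    params: SimulationParams,
    feature_ids: Sequence[str],
    offsets: dict[str, np.ndarray],
    rng: np.random.Generator,
    truth: TruthTable | None = None,
) -> ExpressionMatrix:
    """NB counts X ~ NB(mean = s_j * mu_{g, group(j)}, dispersion phi)."""
    samples = params.sample_ids
    group_idx = np.array([GROUPS.index(params.sample_group[s]) for s in samples])
    baselines = np.exp(
        rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=len(feature_ids))
    )
    if truth is not None and truth.triads:
        # triad members model well-expressed regulators: floor their baseline
        # so counting noise cannot drown the planted coupling
        triad_ids = {fid for t in truth.triads for fid in t[:3]}
        floor = float(np.exp(params.baseline_log_mean + 0.5))
        for i, fid in enumerate(feature_ids):
            if fid in triad_ids:
                baselines[i] = max(baselines[i], floor)
    libsize = (
        np.exp(rng.normal(0.0, params.libsize_log_sd, size=len(samples)))
        if params.libsize_log_sd > 0
        else np.ones(len(samples))
    )
    mu_group = np.empty((len(feature_ids), len(GROUPS)))
    for i, fid in enumerate(feature_ids):
        mu_group[i] = baselines[i] * np.power(2.0, offsets[fid])
    mu = mu_group[:, group_idx] * libsize[None, :]
    phi = params.dispersion
    if phi > 0:
        r = 1.0 / phi
        p = r / (r + mu)
        x = rng.negative_binomial(r, p)
    else:
        x = rng.poisson(mu)
    df = pd.DataFrame(x.astype(float), index=list(feature_ids), columns=samples)
    if truth is not None:
        truth.group_means = {
            fid: {g: float(mu_group[i, gi]) for gi, g in enumerate(GROUPS)}
            for i, fid in enumerate(feature_ids)
        }
    return ExpressionMatrix(df, params.sample_group, kind="counts")


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def simulate_study(params: SimulationParams) -> SimulatedStudy:
    """Generate the complete in-silico study, deterministically from the seed."""
    rng = np.random.default_rng(params.seed)
    records, qtl, feature_class = simulate_annotation(params, rng)
    truth, offsets = plan_truth(params, feature_class, rng)
    triad_mirnas = {mir for _l, mir, _g, _r in truth.triads}
    mirnas, utrs, lnc_seqs, candidate_seqs = simulate_sequences(
        params, records, feature_class, rng, triad_mirnas
    )
    lo, hi = params.sites_per_target
    utr_pairs = [
        (mir, mrna, int(rng.integers(lo, hi + 1)))
        for _lnc, mir, mrna, _role in truth.triads
    ]
    lnc_pairs = [(mir, lnc, 1) for lnc, mir, _mrna, _role in truth.triads]
    utrs, planted_utr = plant_sites(params, mirnas, utrs, utr_pairs, rng)
    lnc_seqs, planted_lnc = plant_sites(params, mirnas, lnc_seqs, lnc_pairs, rng)
    truth.planted_sites = planted_utr + planted_lnc

    feature_ids = sorted(feature_class)
    counts = simulate_counts(params, feature_ids, offsets, rng, truth)

    truth.qtl_members = sorted(
        rec.transcript_id
        for rec in records
        if rec.transcript_id in feature_class and qtl.contains(rec.interval)
    )
    known_ids = {
        rec.transcript_id: rec.biotype
        for rec in records
        if rec.biotype != "novel_candidate"
    }
    return SimulatedStudy(
        params=params,
        records=records,
        qtl=qtl,
        mirnas=mirnas,
        utrs=utrs,
        lnc_seqs=lnc_seqs,
        candidate_seqs=candidate_seqs,
        counts=counts,
        feature_class=feature_class,
        known_ids=known_ids,
        truth=truth,
    )


def write_study(study: SimulatedStudy, out_dir: str | Path, header: str = "") -> None:
    """Emit the study as plain-text inputs consumed by the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_annotation(study.records, out / "annotation.gtf", header=header)
    cio.write_fasta(study.mirnas, out / "mirna.fa")
    cio.write_fasta(study.utrs, out / "utr.fa")
    cio.write_fasta(study.lnc_seqs, out / "lncrna.fa")
    cio.write_fasta(study.candidate_seqs, out / "candidates.fa")
    cio.write_counts(study.counts, out / "counts.tsv", header=header)
    cio.write_groups(study.counts.sample_group, out / "groups.tsv")
    cio.write_bed_interval(study.qtl, out / "qtl.bed", name="ovary_size_qtl")
    with open(out / "feature_class.tsv", "w") as fh:
        for fid in sorted(study.feature_class):
            fh.write(f"{fid}\t{study.feature_class[fid]}\n")
    with open(out / "known_ids.tsv", "w") as fh:
        for fid in sorted(study.known_ids):
            fh.write(f"{fid}\t{study.known_ids[fid]}\n")
    study.truth.to_json(out / "truth.json")
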