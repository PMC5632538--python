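"""Candidate lncRNA classification and the filter cascade.

Novel transcripts survive iff: spliced length >= 200 bp, >= 2 exons,
mean coverage >= 3, assembled in >= 2 samples, no overlap with a known
non-lncRNA annotation, and a noncoding coding-potential call.

Coding potential is a self-contained ORF heuristic (longest forward-frame
ORF >= 300 nt, or covering >= 50% of the transcript, calls the record
coding); an externally supplied call map can override it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .core import Config, SequenceRecord, TranscriptRecord

#: canonical evaluation order of criteria (reports list failures in this order)
CRITERIA = (
    "length",
    "exon_count",
    "coverage",
    "recurrence",
    "known_overlap",
    "coding_potential",
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

ORF_MIN_NT = 300
ORF_MIN_FRACTION = 0.5


@dataclass
class FilterReport:
    transcript_id: str
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_criteria):
            raise ValueError("passed must equal failed_criteria being empty")


def classify_transcripts(
    records: list[TranscriptRecord], known_ids: Mapping[str, str]
) -> list[TranscriptRecord]:
    """Assign biotypes from a known-id map; unmatched records become novel."""
    for rec in records:
        rec.biotype = known_ids.get(rec.transcript_id, "novel_candidate")
    return records


def longest_orf(seq: str) -> int:
    """Length in nt of the longest ORF over the three forward frames.

    An ORF starts at ATG and runs to the first in-frame stop (stop codon
    included) or, if uninterrupted, to the last complete codon.
    """
    seq = seq.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        open_start: int | None = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - open_start)
                open_start = None
            i += 3
        if open_start is not None:  # open ORF runs to last complete codon
            best = max(best, i - open_start)
    return best


def coding_potential_score(seq: SequenceRecord) -> tuple[float, str]:
    """(score, call) where score = longest-ORF length / transcript length.

    call is ``coding`` iff the longest ORF is >= 300 nt or covers >= 50% of
    the transcript; sequences shorter than one codon are noncoding, score 0.
    """
    if len(seq.seq) < 3:
        return 0.0, "noncoding"
    orf = longest_orf(seq.seq)
    score = orf / len(seq.seq)
    call = "coding" if (orf >= ORF_MIN_NT or score >= ORF_MIN_FRACTION) else "noncoding"
    return score, call


def filter_candidates(
    records: list[TranscriptRecord],
    cfg: Config,
    sequences: Mapping[str, SequenceRecord] | None = None,
    coding_calls: Mapping[str, str] | None = None,
) -> tuple[list[TranscriptRecord], list[FilterReport]]:
    """Apply the candidate filter cascade to novel records.

    Only ``novel_candidate`` records are judged.  Every violated criterion
    is listed, in canonical order, so reports are evaluation-order
    independent.  *coding_calls* (id -> coding|noncoding) overrides the ORF
    heuristic; with neither a call nor a sequence the coding criterion is
    not evaluable and does not fail the record.
    """
    sequences = sequences or {}
    coding_calls = coding_calls or {}
    survivors: list[TranscriptRecord] = []
    reports: list[FilterReport] = []
    for rec in records:
        if rec.biotype != "novel_candidate":
            continue
        failed: list[str] = []
        if rec.length() < cfg.min_length:
            failed.append("length")
        if rec.n_exons < cfg.min_exons:
            failed.append("exon_count")
        if rec.coverage < cfg.min_coverage:
            failed.append("coverage")
        if len(rec.present_in_samples) < cfg.min_samples:
            failed.append("recurrence")
        if rec.attrs.get("known_overlap", "").lower() in ("1", "true", "yes"):
            failed.append("known_overlap")
        call = coding_calls.get(rec.transcript_id)
        if call is None and rec.transcript_id in sequences:
            _, call = coding_potential_score(sequences[rec.transcript_id])
        if call == "coding":
            failed.append("coding_potential")
        report = FilterReport(rec.transcript_id, passed=not failed, failed_criteria=failed)
        reports.append(report)
        if report.passed:
            survivors.append(rec)
    return survivors, reports


def write_filter_report(reports: list[FilterReport], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("transcript_id\tpassed\tfailed_criteria\n")
        for r in reports:
            fh.write(
                f"{r.transcript_id}\t{int(r.passed)}\t{','.join(r.failed_criteria)}\n"
            )
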