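"""Core domain types shared across the pipeline.

Coordinate convention: all internal intervals are 0-based, half-open
``[start, end)``.  GTF I/O converts at the boundary (GTF is 1-based,
inclusive); BED I/O is native.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")
DNA_CHARS = set("ACGTN")
RNA_CHARS = set("ACGUN")

GROUPS = ("V", "Q", "C", "R")
#: The three oviposition contrasts, each as (name, treatment, reference).
DEFAULT_CONTRASTS = (("Q_V", "Q", "V"), ("C_Q", "C", "Q"), ("R_C", "R", "C"))

BIOTYPES = ("known_mRNA", "known_lncRNA", "known_other", "novel_candidate")


class CernetError(Exception):
    """Base class for pipeline errors."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptRecord:
    """An assembled transcript: the unit judged by the lncRNA filter cascade."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    coverage: float = 0.0
    present_in_samples: set[str] = field(default_factory=set)
    biotype: str = "novel_candidate"
    attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if not self.interval.contains(e):
                raise ValueError(
                    f"{self.transcript_id}: exon {e} outside transcript interval"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    def length(self) -> int:
        """Spliced length: sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, normalized to upper case."""

    id: str
    seq: str
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError("alphabet must be DNA or RNA")
        self.seq = self.seq.upper()
        allowed = DNA_CHARS if self.alphabet == "DNA" else RNA_CHARS
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "DNA":
            raise ValueError("reverse_complement defined for DNA records")
        return SequenceRecord(
            id=self.id, seq=self.seq.translate(_COMPLEMENT_DNA)[::-1], alphabet="DNA"
        )


class ExpressionMatrix:
    """Non-negative feature x sample matrix with a sample -> group map.

    ``kind`` is one of ``counts``, ``FPKM``, ``TPM``, ``transformed``.
    """

    KINDS = ("counts", "FPKM", "TPM", "transformed")

    def __init__(
        self,
        values: pd.DataFrame,
        sample_group: Mapping[str, str],
        kind: str = "counts",
    ) -> None:
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if kind != "transformed" and np.any(arr < 0):
            raise ValueError("negative values in expression matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in expression matrix")
        missing = [s for s in values.columns if s not in sample_group]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        self.values = values.astype(float)
        self.sample_group = {s: sample_group[s] for s in values.columns}
        self.kind = kind

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_group[s] == group]

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [i for i in ids if i in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.sample_group, self.kind)

    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(self.values[ids], self.sample_group, self.kind)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.sample_group == other.sample_group
            and self.values.equals(other.values)
        )


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: treatment over reference."""

    name: str
    treatment: str
    reference: str

    def __post_init__(self) -> None:
        if self.treatment == self.reference:
            raise ValueError("treatment and reference must differ")


def default_contrasts() -> list[Contrast]:
    return [Contrast(n, t, r) for n, t, r in DEFAULT_CONTRASTS]


def parse_interval(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (0-based half-open, commas allowed)."""
    try:
        chrom, span = text.split(":")
        lo, hi = span.replace(",", "").split("-")
        return GenomicInterval(chrom, int(lo), int(hi))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"cannot parse interval {text!r}: {exc}") from exc


_CONFIG_FIELDS: dict[str, type] = {
    "min_length": int,
    "min_exons": int,
    "min_coverage": float,
    "min_samples": int,
    "alpha": float,
    "r_trans": float,
    "r_pair": float,
    "site_score_min": float,
    "site_energy_max": float,
    "utr_fallback_len": int,
    "qtl_interval": str,
    "qtl_overlap": bool,
    "rng_seed": int,
}


@dataclass
class Config:
    """All pipeline tunables, serializable to a flat ``key=value`` file."""

    min_length: int = 200
    min_exons: int = 2
    min_coverage: float = 3.0
    min_samples: int = 2
    alpha: float = 0.05
    r_trans: float = 0.95
    r_pair: float = 0.8
    site_score_min: float = 140.0
    site_energy_max: float = -10.0
    utr_fallback_len: int = 1000
    qtl_interval: str = "chr11:8900000-12200000"
    qtl_overlap: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.min_length >= 0, "min_length >= 0"),
            (self.min_exons >= 1, "min_exons >= 1"),
            (self.min_coverage >= 0, "min_coverage >= 0"),
            (self.min_samples >= 1, "min_samples >= 1"),
            (0 < self.alpha < 1, "alpha in (0, 1)"),
            (0 < self.r_trans <= 1, "r_trans in (0, 1]"),
            (0 < self.r_pair <= 1, "r_pair in (0, 1]"),
            (self.site_score_min > 0, "site_score_min > 0"),
            (self.site_energy_max < 0, "site_energy_max < 0"),
            (self.utr_fallback_len > 0, "utr_fallback_len > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config violates: {msg}")
        parse_interval(self.qtl_interval)  # validates

    @property
    def qtl(self) -> GenomicInterval:
        return parse_interval(self.qtl_interval)

    def to_text(self) -> str:
        lines = []
        for name in _CONFIG_FIELDS:
            v = getattr(self, name)
            if isinstance(v, bool):
                v = str(v).lower()
            lines.append(f"{name}={v}")
        return "\n".join(lines) + "\n"

    def hash(self) -> str:
        """Short digest of the effective configuration, for output headers."""
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]

    @classmethod
    def from_text(cls, text: str, warn=None) -> "Config":
        kwargs: dict = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value, got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in _CONFIG_FIELDS:
                if warn is not None:
                    warn(f"unknown config key {key!r} ignored")
                continue
            typ = _CONFIG_FIELDS[key]
            try:
                if typ is bool:
                    if val.lower() not in ("true", "false", "0", "1"):
                        raise ValueError(val)
                    kwargs[key] = val.lower() in ("true", "1")
                else:
                    kwargs[key] = typ(val)
            except ValueError as exc:
                raise ValueError(f"config key {key!r}: cannot parse {val!r}") from exc
        return cls(**kwargs)

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)


def geometric_mean(x: np.ndarray) -> float:
    """Geometric mean of strictly positive values."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(math.exp(np.mean(np.log(x))))
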