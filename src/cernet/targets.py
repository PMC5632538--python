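"""Correlation-based trans-target inference and miRNA binding-site scanning.

The site scanner aligns the reversed miRNA against the target region with
pair-complementarity scoring (antiparallel duplex): Watson-Crick pair +5,
G:U wobble +2, mismatch -3, affine gaps (open 8, extend 2), and the score
of columns involving miRNA seed positions 2-8 (from the 5' end) doubled.
Duplex energy comes from a simplified nearest-neighbor stack table.  A site
is retained iff align_score > site_score_min AND energy < site_energy_max.

Exact recurrence (Gotoh local alignment; r = reversed miRNA, t = region):
    M[i][j]  = sub(i, j) + max(0, M[i-1][j-1], Ix[i-1][j-1], Iy[i-1][j-1])
    Ix[i][j] = max(M[i-1][j] - open, Ix[i-1][j] - ext)    # gap in target
    Iy[i][j] = max(M[i][j-1] - open, Iy[i][j-1] - ext)    # gap in miRNA
Site score = max over cells of M (a duplex never ends in a gap).
Non-overlapping sites are taken greedily by descending score (ties by
leftmost position), re-running the DP with taken spans made impassable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import Config, ExpressionMatrix, SequenceRecord, TranscriptRecord

MATCH_SCORE = 5
WOBBLE_SCORE = 2
MISMATCH_SCORE = -3
GAP_OPEN = 8  # cost of the first gap position
GAP_EXT = 2  # cost of each further gap position
SEED_WEIGHT = 2  # multiplier on columns at miRNA positions 2-8
SEED_RANGE = (2, 8)  # 1-based, inclusive, from the miRNA 5' end
MIRNA_LEN_BOUNDS = (18, 26)

# stack energies, kcal/mol
STACK_GC = -3.3
STACK_AU = -1.1
STACK_MIXED = -2.1
STACK_WOBBLE = -1.0

NEG = -(2**30)  # impassable score

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

# pair class of (miRNA base idx, target DNA base idx):
#   2 = GC pair, 1 = AU pair, 3 = G:U wobble, 0 = no pair
_PAIR_CLASS = np.zeros((5, 5), dtype=np.int64)
_PAIR_CLASS[_BASE_INDEX["A"], _BASE_INDEX["T"]] = 1
_PAIR_CLASS[_BASE_INDEX["U"], _BASE_INDEX["A"]] = 1
_PAIR_CLASS[_BASE_INDEX["G"], _BASE_INDEX["C"]] = 2
_PAIR_CLASS[_BASE_INDEX["C"], _BASE_INDEX["G"]] = 2
_PAIR_CLASS[_BASE_INDEX["G"], _BASE_INDEX["T"]] = 3  # G:U wobble
_PAIR_CLASS[_BASE_INDEX["U"], _BASE_INDEX["G"]] = 3

_SUB_BY_CLASS = np.array([MISMATCH_SCORE, MATCH_SCORE, MATCH_SCORE, WOBBLE_SCORE])


@dataclass
class CorrelationEdge:
    a_id: str
    b_id: str
    r: float
    n: int
    edge_class: str  # lnc_trans | mir_mrna | lnc_mir

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-9:
            raise ValueError(f"|r| > 1: {self.r}")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")
        if self.a_id == self.b_id:
            raise ValueError("self-correlation edge")


@dataclass
class BindingSite:
    mirna_id: str
    target_id: str
    target_start: int  # 0-based on the scanned region
    target_end: int
    align_score: float
    energy: float
    alignment: str = ""


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN marks zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        return float("nan")
    return float((dx * dy).sum() / (sx * sy))


def correlation_matrix(a: ExpressionMatrix, b: ExpressionMatrix) -> np.ndarray:
    """All-pairs Pearson r between rows of *a* and rows of *b*.

    Rows with zero variance yield NaN.  Both matrices must carry the same
    samples in the same order.
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("matrices must share identical sample columns")
    n = len(a.sample_ids)
    if n < 3:
        raise ValueError("need >= 3 shared samples")

    def standardized(m: ExpressionMatrix) -> np.ndarray:
        x = m.to_numpy()
        x = x - x.mean(axis=1, keepdims=True)
        s = np.sqrt((x * x).sum(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(s > 0, x / s, np.nan)
        return z

    return standardized(a) @ standardized(b).T


def trans_targets(
    lnc_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix, cfg: Config
) -> tuple[list[CorrelationEdge], int]:
    """lncRNA-mRNA pairs with |Pearson r| >= r_trans (default 0.95).

    Returns the edges and the number of zero-variance features skipped.
    """
    r = correlation_matrix(lnc_expr, mrna_expr)
    n = len(lnc_expr.sample_ids)
    skipped_rows = int(np.isnan(r).all(axis=1).sum()) + int(
        np.isnan(r).all(axis=0).sum()
    )
    edges = []
    with np.errstate(invalid="ignore"):
        hit_i, hit_j = np.where(np.abs(r) >= cfg.r_trans)
    lnc_ids = lnc_expr.feature_ids
    mrna_ids = mrna_expr.feature_ids
    for i, j in zip(hit_i.tolist(), hit_j.tolist()):
        if lnc_ids[i] == mrna_ids[j]:
            continue
        edges.append(
            CorrelationEdge(lnc_ids[i], mrna_ids[j], float(r[i, j]), n, "lnc_trans")
        )
    return edges, skipped_rows


# ---------------------------------------------------------------------------
# Scan-region extraction
# ---------------------------------------------------------------------------

def extract_scan_region(
    record: TranscriptRecord,
    utr_seqs: Mapping[str, SequenceRecord],
    genome: Mapping[str, SequenceRecord] | None,
    cfg: Config,
) -> SequenceRecord | None:
    """The region scanned for miRNA sites: the annotated 3' UTR if present,
    else the window downstream of the stop codon (``stop_pos`` attribute).

    ``stop_pos`` is the genomic boundary immediately downstream of the stop
    codon in transcription direction: plus strand -> window
    [stop_pos, stop_pos + fallback_len); minus strand -> window
    [stop_pos - fallback_len, stop_pos), reverse-complemented.  Windows are
    truncated at chromosome ends with a warning; records with neither a UTR
    nor a stop coordinate are skipped (None) with a warning.
    """
    key = record.transcript_id
    if key in utr_seqs:
        return SequenceRecord(id=key, seq=utr_seqs[key].seq, alphabet="DNA")
    if record.gene_id in utr_seqs:
        return SequenceRecord(id=key, seq=utr_seqs[record.gene_id].seq, alphabet="DNA")
    stop = record.attrs.get("stop_pos")
    if stop is None or genome is None or record.interval.chrom not in genome:
        warnings.warn(f"{key}: no UTR and no usable stop codon; skipped")
        return None
    stop = int(stop)
    chrom = genome[record.interval.chrom]
    flen = cfg.utr_fallback_len
    if record.interval.strand == "-":
        lo, hi = max(0, stop - flen), stop
    else:
        lo, hi = stop, min(len(chrom.seq), stop + flen)
    if hi - lo < flen:
        warnings.warn(f"{key}: downstream window truncated at chromosome end")
    if hi <= lo:
        warnings.warn(f"{key}: empty downstream window; skipped")
        return None
    seq = chrom.seq[lo:hi]
    rec = SequenceRecord(id=key, seq=seq, alphabet="DNA")
    if record.interval.strand == "-":
        rec = rec.reverse_complement()
        rec.id = key
    return rec


# ---------------------------------------------------------------------------
# Site scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)


def _query_profile(mirna_seq: str) -> np.ndarray:
    """Substitution scores per (reversed-query row, target base), seed-weighted."""
    q = mirna_seq.upper().replace("T", "U")
    L = len(q)
    rev = _encode(q[::-1])
    prof = np.empty((L, 5), dtype=np.int64)
    for i in range(L):
        mir_pos = L - i  # 1-based position from the miRNA 5' end
        weight = SEED_WEIGHT if SEED_RANGE[0] <= mir_pos <= SEED_RANGE[1] else 1
        row = _SUB_BY_CLASS[_PAIR_CLASS[rev[i]]] * weight
        row = np.where(_PAIR_CLASS[rev[i]] == 0, MISMATCH_SCORE * weight, row)
        prof[i] = row
        prof[i, 4] = NEG  # sentinel/N never pairs
    return prof


def _check_mirna(mirna: SequenceRecord) -> str:
    lo, hi = MIRNA_LEN_BOUNDS
    if not (lo <= len(mirna.seq) <= hi):
        raise ValueError(
            f"{mirna.id}: miRNA length {len(mirna.seq)} outside [{lo}, {hi}]"
        )
    return mirna.seq.upper().replace("T", "U")


def _best_local_alignment(prof, t_idx, blocked):
    """Best-scoring local alignment via explicit DP with traceback.

    Returns (score, columns) where columns is a list of
    (query_row, target_pos, kind) with kind in {sub, gap_t, gap_q};
    or (NEG, []) when nothing aligns.
    """
    L, n = prof.shape[0], t_idx.size
    M = np.full((L + 1, n + 1), NEG, dtype=np.int64)
    Ix = np.full((L + 1, n + 1), NEG, dtype=np.int64)
    Iy = np.full((L + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, L + 1):
        sub = prof[i - 1][t_idx]
        prev = np.maximum.reduce([M[i - 1, :-1], Ix[i - 1, :-1], Iy[i - 1, :-1]])
        M[i, 1:] = sub + np.maximum(prev, 0)
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - GAP_OPEN, Ix[i - 1, 1:] - GAP_EXT)
        m_row = M[i]
        iy_row = Iy[i]
        for j in range(1, n + 1):  # horizontal state needs the sequential pass
            iy_row[j] = max(m_row[j - 1] - GAP_OPEN, iy_row[j - 1] - GAP_EXT)
            if blocked[j - 1]:
                m_row[j] = NEG
                iy_row[j] = NEG
    score = int(M.max())
    if score <= 0 or score <= NEG // 2:
        return NEG, []
    # ties: leftmost target end, then smallest query row
    flat = np.argwhere(M == score)
    flat = flat[np.lexsort((flat[:, 0], flat[:, 1]))]
    i, j = map(int, flat[0])
    cols: list[tuple[int, int, str]] = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] <= NEG // 2:
                break
            cols.append((i, j, "sub"))
            prev_score = M[i, j] - prof[i - 1][t_idx[j - 1]]
            i, j = i - 1, j - 1
            if prev_score == 0 and max(M[i, j], Ix[i, j], Iy[i, j]) < 0:
                break
            if M[i, j] == prev_score:
                state = "M"
            elif Ix[i, j] == prev_score:
                state = "Ix"
            elif Iy[i, j] == prev_score:
                state = "Iy"
            else:  # local restart
                break
        elif state == "Ix":
            cols.append((i, j, "gap_t"))
            if M[i - 1, j] - GAP_OPEN == Ix[i, j]:
                state = "M"
            i -= 1
        else:  # Iy
            cols.append((i, j, "gap_q"))
            if M[i, j - 1] - GAP_OPEN == Iy[i, j]:
                state = "M"
            j -= 1
    cols.reverse()
    return score, cols


def _site_from_columns(
    mirna: SequenceRecord, region: SequenceRecord, score: int, cols
) -> BindingSite:
    q = mirna.seq.upper().replace("T", "U")
    rev = q[::-1]
    t = region.seq.upper()
    t_positions = [j - 1 for _, j, kind in cols if kind != "gap_t"]
    start, end = min(t_positions), max(t_positions) + 1
    # energy: sum stack energies over consecutive paired columns
    pair_classes = []
    for i, j, kind in cols:
        if kind == "sub":
            cls = int(_PAIR_CLASS[_BASE_INDEX[rev[i - 1]], _BASE_INDEX[t[j - 1]]])
            pair_classes.append(cls)
        else:
            pair_classes.append(-1)  # gap breaks stacking
    energy = 0.0
    for a, b in zip(pair_classes, pair_classes[1:]):
        if a <= 0 or b <= 0:
            continue
        if a == 3 or b == 3:
            energy += STACK_WOBBLE
        elif a == 2 and b == 2:
            energy += STACK_GC
        elif a == 1 and b == 1:
            energy += STACK_AU
        else:
            energy += STACK_MIXED
    q_aln, m_aln, t_aln = [], [], []
    for (i, j, kind), cls in zip(cols, pair_classes):
        if kind == "sub":
            q_aln.append(rev[i - 1])
            t_aln.append(t[j - 1])
            m_aln.append("|" if cls in (1, 2) else (":" if cls == 3 else " "))
        elif kind == "gap_t":
            q_aln.append(rev[i - 1])
            t_aln.append("-")
            m_aln.append(" ")
        else:
            q_aln.append("-")
            t_aln.append(t[j - 1])
            m_aln.append(" ")
    alignment = "".join(q_aln) + "\n" + "".join(m_aln) + "\n" + "".join(t_aln)
    return BindingSite(
        mirna_id=mirna.id,
        target_id=region.id,
        target_start=start,
        target_end=end,
        align_score=float(score),
        energy=energy,
        alignment=alignment,
    )


def scan_mirna_sites(
    mirna: SequenceRecord, region: SequenceRecord, cfg: Config
) -> list[BindingSite]:
    """All retained, non-overlapping binding sites of *mirna* in *region*.

    Sites are extracted greedily by descending alignment score (ties by
    leftmost position): the best local alignment is taken, its target span
    made impassable, and the DP re-run until the best score drops to the
    threshold.  A site is *retained* iff score > site_score_min and energy
    < site_energy_max; spans failing the energy test are still masked so
    the greedy order is deterministic.
    """
    _check_mirna(mirna)
    prof = _query_profile(mirna.seq)
    t_idx = _encode(region.seq.upper())
    blocked = np.zeros(t_idx.size, dtype=bool)
    sites: list[BindingSite] = []
    while True:
        score, cols = _best_local_alignment(prof, t_idx, blocked)
        if score <= cfg.site_score_min or not cols:
            break
        site = _site_from_columns(mirna, region, score, cols)
        blocked[site.target_start : site.target_end] = True
        if site.energy < cfg.site_energy_max:
            sites.append(site)
    sites.sort(key=lambda s: (-s.align_score, s.target_start))
    return sites


def screen_max_scores(
    mirna: SequenceRecord, regions: Sequence[SequenceRecord]
) -> np.ndarray:
    """Best local-alignment score of *mirna* against each region (fast path).

    Regions are concatenated with impassable sentinel blocks and one
    vectorized DP pass is run; per-region maxima equal the per-region DP
    exactly (the sentinel blocks forbid cross-region paths).  Use this to
    short-list regions before running :func:`scan_mirna_sites`.
    """
    seq = _check_mirna(mirna)
    L = len(seq)
    prof = _query_profile(mirna.seq)
    spacer = np.full(L + 1, 4, dtype=np.int64)
    chunks, bounds = [], []
    pos = 0
    for reg in regions:
        enc = _encode(reg.seq.upper())
        chunks.append(enc)
        bounds.append((pos, pos + enc.size))
        pos += enc.size
        chunks.append(spacer)
        pos += spacer.size
    if not chunks:
        return np.zeros(0)
    t_idx = np.concatenate(chunks)
    n = t_idx.size
    sentinel = t_idx == 4
    j_ext = np.arange(n, dtype=np.int64) * GAP_EXT

    m_prev = np.full(n + 1, NEG, dtype=np.int64)
    ix_prev = np.full(n + 1, NEG, dtype=np.int64)
    iy_prev = np.full(n + 1, NEG, dtype=np.int64)
    col_best = np.full(n, NEG, dtype=np.int64)
    m_row = np.full(n + 1, NEG, dtype=np.int64)
    for i in range(1, L + 1):
        sub = prof[i - 1][t_idx]
        prev = np.maximum.reduce([m_prev[:-1], ix_prev[:-1], iy_prev[:-1]])
        np.maximum(prev, 0, out=prev)
        m_row = np.empty(n + 1, dtype=np.int64)
        m_row[0] = NEG
        m_row[1:] = sub + prev
        m_row[1:][sentinel] = NEG
        ix_row = np.empty(n + 1, dtype=np.int64)
        ix_row[0] = NEG
        ix_row[1:] = np.maximum(m_prev[1:] - GAP_OPEN, ix_prev[1:] - GAP_EXT)
        # Iy closed form; sentinel columns reset the running max (impassable)
        B = m_row[:-1] + j_ext
        B = np.where(np.concatenate(([False], sentinel[:-1])), NEG, B)
        # segmented running max: reset at sentinel starts
        runmax = _segmented_running_max(B, np.concatenate(([False], sentinel[:-1])))
        iy_row = np.empty(n + 1, dtype=np.int64)
        iy_row[0] = NEG
        iy_row[1:] = runmax - GAP_OPEN - j_ext
        iy_row[1:][sentinel] = NEG
        np.maximum(col_best, m_row[1:], out=col_best)
        m_prev, ix_prev, iy_prev = m_row, ix_row, iy_row
    out = np.empty(len(regions), dtype=float)
    for k, (lo, hi) in enumerate(bounds):
        out[k] = col_best[lo:hi].max() if hi > lo else NEG
    return out


def _segmented_running_max(values: np.ndarray, reset: np.ndarray) -> np.ndarray:
    """Running max that restarts (from NEG) wherever *reset* is True.

    Implemented with an offset trick so it stays vectorized: within each
    segment the plain cumulative max applies; across resets the carried
    value is forced below any real score.
    """
    seg_id = np.cumsum(reset)
    # later segments get a larger additive offset, so earlier segments'
    # maxima are forced far below any value of the current segment
    offset = seg_id * np.int64(2**40)
    shifted = values.astype(np.int64) + offset
    run = np.maximum.accumulate(shifted)
    return run - offset


# ---------------------------------------------------------------------------
# Batch scanning driver
# ---------------------------------------------------------------------------

def scan_many(
    mirnas: Sequence[SequenceRecord],
    regions: Sequence[SequenceRecord],
    cfg: Config,
) -> list[BindingSite]:
    """Scan every miRNA against every region, screening first for speed.

    Results are identical to running :func:`scan_mirna_sites` on every
    pair (the screen is an exact per-region score bound from the same DP).
    """
    sites: list[BindingSite] = []
    for mir in mirnas:
        if 5 * len(mir.seq) + MATCH_SCORE * 7 <= cfg.site_score_min:
            # even a perfect full-length duplex cannot pass the threshold
            continue
        best = screen_max_scores(mir, regions)
        for k in np.nonzero(best > cfg.site_score_min)[0]:
            sites.extend(scan_mirna_sites(mir, regions[int(k)], cfg))
    sites.sort(key=lambda s: (s.mirna_id, s.target_id, s.target_start))
    return sites


def write_sites(sites: Sequence[BindingSite], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("mirna\ttarget\tstart\tend\tscore\tenergy\n")
        for s in sites:
            fh.write(
                f"{s.mirna_id}\t{s.target_id}\t{s.target_start}\t{s.target_end}"
                f"\t{s.align_score:g}\t{s.energy:.2f}\n"
            )


def write_edges(edges: Sequence[CorrelationEdge], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("a\tb\tr\tn\tclass\n")
        for e in sorted(edges, key=lambda e: (e.a_id, e.b_id)):
            fh.write(f"{e.a_id}\t{e.b_id}\t{e.r:.6f}\t{e.n}\t{e.edge_class}\n")
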