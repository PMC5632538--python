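"""Normalization, negative-binomial two-group testing, BH correction,
expression transforms, sample clustering, and the qPCR quantity helper.

The NB test is a compact reimplementation of the classic count-based
workflow: median-of-ratios size factors, method-of-moments dispersion with
shrinkage toward the mean trend, and a Wald test on the log2 fold change.
Calibration is enforced by simulation tests rather than by matching any
particular external implementation numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .core import Config, Contrast, ExpressionMatrix

LOG10_EPS = 1e-2  # guards log10(0) in the published transform
LFC_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8
DISPERSION_SHRINKAGE = 0.5  # weight on the per-feature moment estimate


@dataclass
class DEResult:
    feature_id: str
    contrast: Contrast
    base_mean: float
    log2fc: float
    p: float
    q: float
    direction: str  # up | down | ns

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")
        if self.q < self.p - 1e-12:
            raise ValueError("q must be >= p")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors(counts: ExpressionMatrix) -> dict[str, float]:
    """Median-of-ratios size factors.

    For each feature with all-positive counts, the per-sample ratio to the
    feature's geometric mean across samples is taken; the size factor is
    the per-sample median of those ratios (reported unscaled).
    """
    if counts.kind != "counts":
        raise ValueError("size factors are defined on raw counts")
    x = counts.to_numpy()
    positive = np.all(x > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "use a pseudo-reference fallback or filter samples"
        )
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1, keepdims=True)
    ratios = np.exp(logx - log_geomean)
    factors = np.median(ratios, axis=0)
    return dict(zip(counts.sample_ids, factors.astype(float)))


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


# ---------------------------------------------------------------------------
# NB two-group Wald test
# ---------------------------------------------------------------------------

def nb_test_contrast(
    counts: ExpressionMatrix,
    contrast: Contrast,
    cfg: Config,
    factors: Mapping[str, float] | None = None,
) -> list[DEResult]:
    """Two-group NB Wald test for one contrast, all features reported.

    Per feature: counts are divided by size factors; the dispersion is a
    method-of-moments estimate from pooled within-group moments, shrunk
    halfway toward the across-feature mean and floored; the Wald statistic
    is log2fc / SE with SE from the delta method on the NB variance
    mu + phi*mu^2.  BH q-values are computed over the tested family.
    """
    a_samples = counts.group_samples(contrast.reference)
    b_samples = counts.group_samples(contrast.treatment)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(f"{contrast.name}: both groups need >= 2 samples")
    if factors is None:
        factors = size_factors(counts)
    s = np.array([factors[smp] for smp in counts.sample_ids])
    y = counts.to_numpy() / s  # normalized counts
    cols = {smp: i for i, smp in enumerate(counts.sample_ids)}
    ya = y[:, [cols[smp] for smp in a_samples]]
    yb = y[:, [cols[smp] for smp in b_samples]]
    n_a, n_b = ya.shape[1], yb.shape[1]

    m_a = ya.mean(axis=1)
    m_b = yb.mean(axis=1)
    base_mean = np.concatenate([ya, yb], axis=1).mean(axis=1)

    # pooled within-group moments -> moment dispersion, shrunk to the trend mean
    var_a = ya.var(axis=1, ddof=1)
    var_b = yb.var(axis=1, ddof=1)
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    pooled_mean = (n_a * m_a + n_b * m_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(
            pooled_mean > 0, (pooled_var - pooled_mean) / pooled_mean**2, 0.0
        )
    phi_raw = np.maximum(phi_raw, 0.0)
    phi = DISPERSION_SHRINKAGE * phi_raw + (1 - DISPERSION_SHRINKAGE) * phi_raw.mean()
    phi = np.maximum(phi, DISPERSION_FLOOR)

    log2fc = np.log2((m_b + LFC_PSEUDOCOUNT) / (m_a + LFC_PSEUDOCOUNT))
    v_a = (m_a + phi * m_a**2) / n_a
    v_b = (m_b + phi * m_b**2) / n_b
    se2 = (
        v_a / (m_a + LFC_PSEUDOCOUNT) ** 2 + v_b / (m_b + LFC_PSEUDOCOUNT) ** 2
    ) / np.log(2) ** 2
    se = np.sqrt(se2)

    both_zero = (m_a + m_b) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(both_zero | (se == 0), 1.0, p)
    p = np.clip(p, 0.0, 1.0)

    if np.all(ya == 0) or np.all(yb == 0):
        warnings.warn(
            f"{contrast.name}: one group has all-zero counts for every feature"
        )

    q = np.asarray(bh_adjust(p.tolist()))
    results = []
    for i, fid in enumerate(counts.feature_ids):
        if q[i] < cfg.alpha and log2fc[i] > 0:
            direction = "up"
        elif q[i] < cfg.alpha and log2fc[i] < 0:
            direction = "down"
        else:
            direction = "ns"
        results.append(
            DEResult(
                feature_id=fid,
                contrast=contrast,
                base_mean=float(base_mean[i]),
                log2fc=float(log2fc[i]),
                p=float(p[i]),
                q=float(q[i]),
                direction=direction,
            )
        )
    return results


def run_de(
    counts: ExpressionMatrix,
    contrasts: Sequence[Contrast],
    feature_class: Mapping[str, str],
    cfg: Config,
) -> dict[str, dict[str, list[DEResult]]]:
    """Run all contrasts separately per RNA class (BH within class x contrast).

    Size factors are computed per class, mirroring separately prepared
    libraries.  Returns results[contrast.name][rna_class].
    """
    classes = sorted(set(feature_class.values()))
    out: dict[str, dict[str, list[DEResult]]] = {c.name: {} for c in contrasts}
    for cls in classes:
        ids = [f for f in counts.feature_ids if feature_class.get(f) == cls]
        if not ids:
            continue
        sub = counts.subset_features(ids)
        factors = size_factors(sub)
        for contrast in contrasts:
            out[contrast.name][cls] = nb_test_contrast(sub, contrast, cfg, factors)
    return out


def de_feature_sets(
    results: dict[str, dict[str, list[DEResult]]]
) -> dict[str, set[str]]:
    """Significant feature ids per contrast (union over classes)."""
    out: dict[str, set[str]] = {}
    for cname, per_class in results.items():
        out[cname] = {
            r.feature_id
            for res in per_class.values()
            for r in res
            if r.direction != "ns"
        }
    return out


# ---------------------------------------------------------------------------
# Expression transforms
# ---------------------------------------------------------------------------

def transform_expression(
    counts: ExpressionMatrix, lengths: Mapping[str, int], kind: str
) -> ExpressionMatrix:
    """log10-shifted FPKM or TPM: value = log10(v + 1e-2) + 1.

    FPKM_gj = X_gj / (len_g/1e3 * N_j/1e6), N_j the column sum;
    TPM_gj = 1e6 * (X_gj/len_g) / sum_g(X_gj/len_g).
    """
    if kind not in ("FPKM", "TPM"):
        raise ValueError("kind must be FPKM or TPM")
    lens = np.array([lengths[f] for f in counts.feature_ids], dtype=float)
    if np.any(lens <= 0):
        raise ValueError("zero-length feature")
    x = counts.to_numpy()
    if kind == "FPKM":
        n = x.sum(axis=0)
        if np.any(n <= 0):
            raise ValueError("sample with zero total counts")
        v = x / (lens[:, None] / 1e3 * n[None, :] / 1e6)
    else:
        rate = x / lens[:, None]
        denom = rate.sum(axis=0)
        if np.any(denom <= 0):
            raise ValueError("sample with zero total counts")
        v = 1e6 * rate / denom[None, :]
    transformed = np.log10(v + LOG10_EPS) + 1.0
    df = pd.DataFrame(transformed, index=counts.feature_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, counts.sample_group, kind="transformed")


# ---------------------------------------------------------------------------
# Hierarchical sample clustering
# ---------------------------------------------------------------------------

def cluster_samples(mat: ExpressionMatrix) -> tuple[str, np.ndarray, list[str]]:
    """Complete-linkage clustering of samples on Euclidean distance.

    Samples are sorted lexicographically first, making output invariant to
    input order (deterministic tie-breaking).  Returns (newick, linkage
    matrix, leaf order); Newick branch lengths are merge-height increments.
    """
    if mat.kind != "transformed":
        raise ValueError("clustering expects a transformed matrix")
    samples = sorted(mat.sample_ids)
    if len(samples) < 2:
        raise ValueError("clustering needs >= 2 samples")
    x = mat.subset_samples(samples).to_numpy().T  # samples x features
    z = linkage(pdist(x, metric="euclidean"), method="complete")
    newick = linkage_to_newick(z, samples)
    return newick, z, samples


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as Newick with height-difference branches."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        left, right, height = int(z[node - n, 0]), int(z[node - n, 1]), z[node - n, 2]
        parts = []
        for child in sorted((left, right)):
            bl = height - heights[child]
            parts.append(f"{render(child)}:{bl:.6g}")
        heights[node] = height
        return "(" + ",".join(parts) + ")"

    for idx in range(len(z)):
        node = n + idx
        heights[node] = z[idx, 2]
    return render(n + len(z) - 1) + ";"


# ---------------------------------------------------------------------------
# qPCR helper
# ---------------------------------------------------------------------------

def qpcr_relative_quantity(
    ct_target: float,
    ct_reference: float,
    slope: float,
    calibrator_mean: float = 1.0,
) -> float:
    """Standard-curve relative quantity 10^(-dCt/slope), calibrated.

    dCt = ct_target - ct_reference; the result is divided by
    *calibrator_mean* so the calibrator group averages 1.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero")
    if calibrator_mean <= 0:
        raise ValueError("calibrator_mean must be positive")
    dct = ct_target - ct_reference
    return 10.0 ** (-dct / slope) / calibrator_mean
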