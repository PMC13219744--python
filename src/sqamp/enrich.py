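"""Negative-binomial differential abundance between two conditions.

A deliberately simple DESeq2-like test: median-of-ratios size factors,
per-feature method-of-moments dispersion pooled across the two groups, a
Wald statistic on the log2 fold-change with a delta-method standard error
from the NB variance, and two-sided normal p-values.  No dispersion or
fold-change shrinkage and no outlier handling.  Significance follows the
raw p < alpha rule (default alpha 0.01); Benjamini-Hochberg q-values are
reported alongside for users who prefer FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import CountMatrix

LOG2 = np.log(2.0)


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors (one per sample).

    factor_s = median over features with all-positive counts of
    count[f, s] / geometric_mean(count[f, :]).  If no feature is positive in
    every sample, falls back to total-count scaling (factors proportional to
    library size, geometric mean 1).
    """
    X = matrix.counts.to_numpy(dtype=float)
    pos = (X > 0).all(axis=1)
    if pos.any():
        geo = np.exp(np.mean(np.log(X[pos]), axis=1, keepdims=True))
        sf = np.median(X[pos] / geo, axis=0)
    else:
        import warnings
        warnings.warn("no feature with all-positive counts; "
                      "falling back to total-count size factors")
        tot = X.sum(axis=0)
        if (tot <= 0).any():
            raise ValueError("sample with zero total count")
        sf = tot / np.exp(np.mean(np.log(tot)))
    return pd.Series(sf, index=matrix.samples, name="size_factor")


@dataclass
class EnrichmentResult:
    feature: str
    baseMean: float
    log2fc: float
    se: float
    wald_p: float
    bh_q: float
    significant: bool


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def nb_wald_test(matrix: CountMatrix, treated: str = "treated",
                 control: str = "control", alpha: float = 0.01,
                 dispersion_floor: float = 1e-8,
                 shared_dispersion: bool = True) -> pd.DataFrame:
    """Per-feature Wald test of treated vs control mean abundance.

    Counts are normalized by size factors; the NB dispersion is estimated by
    method of moments on normalized counts, pooling the within-group residual
    variance across both groups.  With shared_dispersion=True (default) each
    feature's dispersion is floored at the across-feature mean dispersion
    (a conservative pooling in the spirit of edgeR's common dispersion):
    with few replicates the raw per-feature estimate has so few degrees of
    freedom that a normal Wald test becomes strongly anti-conservative.
    log2fc uses a 0.5 pseudocount so all-zero groups stay finite.  Returns a
    DataFrame ordered by p-value with columns matching
    :class:`EnrichmentResult`.
    """
    groups = {s: c for s, c in matrix.condition.items()}
    t_samples = [s for s in matrix.samples if groups.get(s) == treated]
    c_samples = [s for s in matrix.samples if groups.get(s) == control]
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("need >=2 samples per condition")
    sf = size_factors(matrix)
    X = matrix.counts.to_numpy(dtype=float)
    samples = matrix.samples
    ti = [samples.index(s) for s in t_samples]
    ci = [samples.index(s) for s in c_samples]
    Z = X / sf.to_numpy()[None, :]
    Zt, Zc = Z[:, ti], Z[:, ci]
    nt, nc = len(ti), len(ci)
    mt, mc = Zt.mean(axis=1), Zc.mean(axis=1)

    # pooled within-group variance of normalized counts
    ss = ((Zt - mt[:, None]) ** 2).sum(axis=1) + ((Zc - mc[:, None]) ** 2).sum(axis=1)
    v = ss / (nt + nc - 2)
    m_pool = (nt * mt + nc * mc) / (nt + nc)
    # E[var(K/sf)] ~ m * mean(1/sf) + disp * m^2  (method of moments)
    inv_sf = float(np.mean(1.0 / sf.to_numpy()[ti + ci]))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (v - m_pool * inv_sf) / np.square(m_pool)
    disp = np.where(np.isfinite(disp), disp, dispersion_floor)
    disp = np.maximum(disp, dispersion_floor)
    if shared_dispersion:
        informative = m_pool > 0
        if informative.any():
            common = max(float(disp[informative].mean()), dispersion_floor)
            disp = np.maximum(disp, common)

    # delta-method SE of the log2 fold-change; the 0.5 pseudocount enters
    # only when a group mean is zero, so fold-changes on all-positive
    # features are exactly invariant to per-sample count rescaling
    inv_t = (1.0 / sf.to_numpy()[ti])
    inv_c = (1.0 / sf.to_numpy()[ci])
    var_mt = (mt[:, None] * inv_t[None, :] + disp[:, None] * np.square(mt)[:, None]).sum(axis=1) / nt**2
    var_mc = (mc[:, None] * inv_c[None, :] + disp[:, None] * np.square(mc)[:, None]).sum(axis=1) / nc**2
    pt = np.where(mt > 0, 0.0, 0.5)
    pc = np.where(mc > 0, 0.0, 0.5)
    log2fc = np.log2(mt + pt) - np.log2(mc + pc)
    se = np.sqrt(var_mt / np.square(mt + pt) + var_mc / np.square(mc + pc)) / LOG2
    zero = (mt + mc) == 0
    se = np.where(se > 0, se, np.inf)
    z = np.where(zero, 0.0, log2fc / se)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(zero, 1.0, p)
    log2fc = np.where(zero, 0.0, log2fc)
    q = _bh_adjust(p)
    base_mean = Z.mean(axis=1)
    df = pd.DataFrame({
        "feature": matrix.features,
        "baseMean": base_mean,
        "log2fc": log2fc,
        "se": np.where(np.isfinite(se), se, np.nan),
        "wald_p": p,
        "bh_q": q,
        "significant": p < alpha,
    })
    return df.sort_values("wald_p", kind="stable").reset_index(drop=True)
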