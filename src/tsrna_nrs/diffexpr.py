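"""Simplified negative-binomial differential testing.

Counts are modelled as NB with variance mu + alpha*mu^2. Normalisation is
median-of-ratios; the per-feature dispersion alpha is a method-of-moments
estimate pooled across the two conditions (no shrinkage); the test is a
Wald statistic on log2 of pseudocounted normalised condition means with a
delta-method standard error. Because the SE is estimated from very few
replicates, p-values are taken from a t reference with nA+nB-2 degrees of
freedom rather than the normal. Multiple testing is Benjamini-Hochberg.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The pseudo-reference is the per-feature geometric mean over samples,
    using features with strictly positive counts everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[0] == 0:
        raise ValueError("empty count matrix")
    if (mat.sum(axis=0) == 0).any():
        bad = counts.columns[mat.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature with nonzero counts in every sample")
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_test(
    counts: pd.DataFrame,
    condition_labels: Sequence[str],
    reference: str | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature NB Wald test between two conditions.

    ``condition_labels`` aligns with the columns of ``counts``; log2 fold
    change is treatment over ``reference`` (default: the first label seen).
    Returns a DataFrame indexed like ``counts`` with columns ``baseMean``,
    ``log2FoldChange``, ``pvalue``, ``padj``.
    """
    labels = list(condition_labels)
    if len(labels) != counts.shape[1]:
        raise ValueError("condition_labels must match count columns")
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {levels}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among conditions {levels}")
    treatment = next(l for l in levels if l != reference)
    mask_a = np.array([l == reference for l in labels])
    mask_b = ~mask_a
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each condition needs >= 2 replicates")

    sf = size_factors(counts).to_numpy()
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    a, b = norm[:, mask_a], norm[:, mask_b]
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    v_a, v_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(m_a > 0, (v_a - m_a) / np.square(m_a), 0.0)
        alpha_b = np.where(m_b > 0, (v_b - m_b) / np.square(m_b), 0.0)
    alpha = np.maximum((alpha_a + alpha_b) / 2.0, DISPERSION_FLOOR)

    # difference of logs so that swapping conditions negates lfc exactly
    lfc = np.log2(m_b + pseudocount) - np.log2(m_a + pseudocount)
    var_ma = (m_a + alpha * np.square(m_a)) / n_a
    var_mb = (m_b + alpha * np.square(m_b)) / n_b
    se = np.sqrt(var_ma / np.square(m_a + pseudocount) + var_mb / np.square(m_b + pseudocount)) / LN2

    df = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvalue = 2.0 * stats.t.sf(np.abs(z), df)
    pvalue = np.clip(pvalue, 0.0, 1.0)
    padj = multipletests(pvalue, method="fdr_bh")[1] if len(pvalue) else pvalue

    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FoldChange": lfc,
            "pvalue": pvalue,
            "padj": np.maximum(padj, pvalue),
        },
        index=counts.index,
    ).assign(condition=f"{treatment}_vs_{reference}")


def classify_de(results: pd.DataFrame, alpha: float, direction: str = "both") -> set[str]:
    """Feature ids significant at FDR ``alpha`` with the given sign.

    ``direction``: ``up`` (log2FC > 0), ``down`` (log2FC < 0) or ``both``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if results.empty:
        return set()
    sig = results["padj"] < alpha
    if direction == "up":
        sig &= results["log2FoldChange"] > 0
    elif direction == "down":
        sig &= results["log2FoldChange"] < 0
    return set(results.index[sig])
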