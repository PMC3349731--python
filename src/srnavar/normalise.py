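"""Size-factor normalisation, log transform, and PC-covariate batch screen.

Library sizes are equalised with median-of-ratios size factors: for library j,
``s_j = median_g ( n_gj / GM_g )`` where ``GM_g`` is the geometric mean of
gene g across libraries and genes with any zero count are excluded from the
median.  Expression values are ``log2((n_gj + pseudocount) / s_j)``.

Batch effects are screened by correlating sample principal components with
known covariates; the test statistic is ``t = r * sqrt((n-2) / (1-r^2))`` on
``n-2`` degrees of freedom, Bonferroni-corrected over the number of tests
(one per component, following the study's convention of using the sample
count as the denominator).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Requires at least two samples and at least one gene with all-positive
    counts; genes containing zeros are excluded from the median.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts")
    sub = mat[positive]
    log_gm = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_gm[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def log_normalise(counts: pd.DataFrame, s: pd.Series,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """log2((n + pseudocount) / s_j) expression matrix."""
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("size factors must be positive and finite")
    s = s.reindex(counts.columns)
    return np.log2(counts.add(pseudocount).div(s, axis=1))


def critical_r(n_samples: int, n_tests: int | None = None,
               alpha: float = 0.05) -> float:
    """The |r| boundary at which a PC-covariate correlation becomes
    significant after Bonferroni correction.

    Solves ``2 * sf_t(r * sqrt((n-2)/(1-r^2)); n-2) * n_tests = alpha``.
    """
    if n_tests is None:
        n_tests = n_samples
    df = n_samples - 2
    t_crit = stats.t.isf(alpha / n_tests / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit ** 2))


def sample_pcs(expr: pd.DataFrame, n_pcs: int | None = None) -> pd.DataFrame:
    """Principal components of samples from the centred expression matrix.

    Rows of ``expr`` are RNAs, columns samples.  Components are ordered by
    explained variance; scores are returned per sample.
    """
    X = expr.to_numpy(dtype=float).T          # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(X, full_matrices=False)
    scores = u * sv
    if n_pcs is None:
        n_pcs = min(scores.shape[1], 20)
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return pd.DataFrame(scores[:, :n_pcs], index=expr.columns, columns=cols)


def _encode_covariate(values: pd.Series) -> pd.DataFrame:
    if pd.api.types.is_numeric_dtype(values):
        return values.to_frame()
    return pd.get_dummies(values, prefix=values.name, dtype=float)


def pc_covariate_screen(expr: pd.DataFrame, covariates: pd.DataFrame,
                        n_pcs: int | None = None, alpha: float = 0.05,
                        n_tests: int | None = None) -> pd.DataFrame:
    """Correlate sample PCs with covariates and report significant pairs.

    Categorical covariates are one-hot encoded and scored by the level with
    maximal |r|.  The Bonferroni denominator defaults to the sample count.
    Returns a table of (PC, covariate, r, p, p_bonferroni, significant).
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least three samples")
    pcs = sample_pcs(expr, n_pcs)
    if n_tests is None:
        n_tests = n
    df = n - 2
    rows = []
    for cov_name in covariates.columns:
        enc = _encode_covariate(covariates[cov_name].loc[pcs.index])
        enc = enc.to_numpy(dtype=float)
        if np.allclose(enc.std(axis=0), 0):
            warnings.warn(f"covariate {cov_name!r} is constant; skipped")
            continue
        keep = enc.std(axis=0) > 0
        enc = enc[:, keep]
        for pc in pcs.columns:
            y = pcs[pc].to_numpy()
            rs = [float(np.corrcoef(y, enc[:, j])[0, 1])
                  for j in range(enc.shape[1])]
            r = max(rs, key=abs)
            t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df))
            p_adj = min(1.0, p * n_tests)
            rows.append((pc, cov_name, r, p, p_adj, p_adj < alpha))
    return pd.DataFrame(rows, columns=["pc", "covariate", "r", "p",
                                       "p_bonferroni", "significant"])
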