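"""Likelihood-ratio association of small-RNA expression with genotype and
phenotype, with Storey q-value FDR control.

Each test compares two nested Gaussian linear models — covariates only
versus covariates plus the predictor — using ``-2 log(likelihood ratio) =
n * ln(RSS_null / RSS_full)`` referred to a chi-squared distribution with one
degree of freedom.  Covariates follow the study design: age numeric, library
batch and multiplexing tag one-hot encoded.  cis-eQTL scans test every
retained SNP within 100 kb of the transcript; q-values are computed over the
pooled test list.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

CIS_WINDOW = 100_000
MIN_MAF = 0.05
MIN_INFO = 0.8
LEAN_MAX_BMI = 25.0
OBESE_MIN_BMI = 30.0


def encode_covariates(covariates: pd.DataFrame | None,
                      index=None) -> np.ndarray:
    """Design matrix with intercept; categoricals one-hot, first level as
    reference."""
    if covariates is None or covariates.empty:
        n = len(index) if index is not None else 0
        return np.ones((n, 1))
    if index is not None:
        covariates = covariates.loc[index]
    cols = [np.ones(len(covariates))]
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
    return np.column_stack(cols)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def lrt_linear(y, x, covariates: np.ndarray | None = None):
    """Gaussian likelihood-ratio test for a single predictor.

    Returns ``(stat, p, sign)`` where ``stat = n * ln(RSS_null / RSS_full)``,
    p is the chi-squared(1) upper tail, and sign is the sign of the fitted
    predictor coefficient.  Raises ValueError if the predictor is collinear
    with the covariates.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if covariates is None:
        covariates = np.ones((n, 1))
    X_full = np.column_stack([covariates, x])
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(covariates):
        raise ValueError("predictor collinear with covariates")
    rss0, _ = _rss(y, covariates)
    rss1, beta = _rss(y, X_full)
    if rss1 <= 0:
        return float("inf"), 5e-324, float(np.sign(beta[-1]))
    stat = n * np.log(rss0 / rss1)
    p = float(stats.chi2.sf(stat, df=1))
    p = max(p, 5e-324)
    return float(stat), p, float(np.sign(beta[-1]))


def qvalues(pvals, pi0: float | None = None,
            lambdas=None) -> np.ndarray:
    """Storey q-values with smoother-estimated pi0.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is evaluated on a grid
    and smoothed with a cubic polynomial; the smoothed value at the largest
    lambda (clipped to (0, 1]) estimates pi0.  Then
    ``q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j)``, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        p = np.clip(p, 5e-324, 1.0)
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas)
        if m < 100:
            pi0 = 1.0
        else:
            pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
            coeffs = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coeffs, lambdas.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def cis_eqtl_scan(expr: pd.DataFrame, genotypes: pd.DataFrame,
                  snp_info: pd.DataFrame, annotations: pd.DataFrame,
                  covariates: pd.DataFrame | None = None,
                  window: int = CIS_WINDOW, min_maf: float = MIN_MAF,
                  min_info: float = MIN_INFO) -> pd.DataFrame:
    """Likelihood-ratio cis-eQTL scan.

    ``expr``: RNA x sample log expression.  ``genotypes``: SNP x sample
    dosages in [0, 2].  ``snp_info``: per-SNP ``chrom``, ``pos``, ``maf``,
    ``info``.  ``annotations``: per-RNA ``chrom``, ``start``, ``end``.
    Tests every retained SNP within ``window`` of the transcript; q-values
    are computed over the pooled list of tests.
    """
    samples = [s for s in expr.columns if s in genotypes.columns]
    cov = encode_covariates(covariates, index=samples)
    retained = snp_info[(snp_info["maf"] > min_maf)
                        & (snp_info["info"] > min_info)]
    rows = []
    for rna in expr.index:
        if rna not in annotations.index:
            warnings.warn(f"RNA {rna!r} has no annotation; skipped")
            continue
        ann = annotations.loc[rna]
        near = retained[(retained["chrom"] == ann["chrom"])
                        & (retained["pos"] >= ann["start"] - window)
                        & (retained["pos"] <= ann["end"] + window)]
        y = expr.loc[rna, samples].to_numpy(dtype=float)
        for snp in near.index:
            x = genotypes.loc[snp, samples].to_numpy(dtype=float)
            try:
                stat, p, sign = lrt_linear(y, x, cov)
            except ValueError:
                warnings.warn(f"SNP {snp!r} collinear with covariates; skipped")
                continue
            rows.append((rna, snp, sign, stat, p))
    result = pd.DataFrame(rows, columns=["feature", "predictor", "sign",
                                         "stat", "p"])
    if len(result):
        result["q"] = qvalues(result["p"].to_numpy())
    else:
        result["q"] = []
    return result.sort_values("p").reset_index(drop=True)


def phenotype_assoc(expr: pd.DataFrame, phenotypes: pd.DataFrame,
                    covariates: pd.DataFrame | None = None,
                    max_missing: float = 0.2,
                    insulin_floor: tuple[str, float, float] | None =
                    ("insulin", 13.0, 12.0)) -> dict[str, pd.DataFrame]:
    """Per-trait LRT association tables, q-values computed per trait.

    Fasting insulin values below the assay detection limit are floored
    (values < 13 set to 12) before testing, matching the study convention.
    Traits with more than ``max_missing`` missing values are skipped.
    """
    out: dict[str, pd.DataFrame] = {}
    for trait in phenotypes.columns:
        vals = phenotypes[trait].copy()
        if insulin_floor and trait == insulin_floor[0]:
            vals = vals.where(~(vals < insulin_floor[1]), insulin_floor[2])
        if vals.isna().mean() > max_missing:
            warnings.warn(f"trait {trait!r} has too many missing values; skipped")
            continue
        keep = vals.notna()
        samples = [s for s in expr.columns if keep.get(s, False)]
        if vals.loc[samples].nunique() < 2:
            raise ValueError(f"trait {trait!r} is constant")
        cov = encode_covariates(covariates, index=samples)
        x = vals.loc[samples].to_numpy(dtype=float)
        rows = []
        for rna in expr.index:
            y = expr.loc[rna, samples].to_numpy(dtype=float)
            stat, p, sign = lrt_linear(y, x, cov)
            rows.append((rna, trait, sign, stat, p))
        table = pd.DataFrame(rows, columns=["feature", "predictor", "sign",
                                            "stat", "p"])
        table["q"] = qvalues(table["p"].to_numpy())
        out[trait] = table.sort_values("p").reset_index(drop=True)
    return out


def group_contrast(expr: pd.DataFrame, bmi: pd.Series,
                   covariates: pd.DataFrame | None = None,
                   lean_max: float = LEAN_MAX_BMI,
                   obese_min: float = OBESE_MIN_BMI) -> pd.DataFrame:
    """Lean (BMI < lean_max) versus obese (BMI > obese_min) expression LRT.

    Subjects in between are excluded; both groups must be non-empty.
    """
    lean = bmi.index[bmi < lean_max]
    obese = bmi.index[bmi > obese_min]
    if len(lean) == 0 or len(obese) == 0:
        raise ValueError("lean or obese group is empty")
    samples = [s for s in expr.columns if s in lean.union(obese)]
    group = np.array([1.0 if s in set(obese) else 0.0 for s in samples])
    cov = encode_covariates(covariates, index=samples)
    rows = []
    for rna in expr.index:
        y = expr.loc[rna, samples].to_numpy(dtype=float)
        stat, p, sign = lrt_linear(y, group, cov)
        rows.append((rna, "lean_obese", sign, stat, p))
    table = pd.DataFrame(rows, columns=["feature", "predictor", "sign",
                                        "stat", "p"])
    table["q"] = qvalues(table["p"].to_numpy())
    return table.sort_values("p").reset_index(drop=True)


def arm_analysis(mature_expr: pd.DataFrame, star_expr: pd.DataFrame,
                 genotypes: pd.DataFrame | None = None,
                 snp_info: pd.DataFrame | None = None,
                 annotations: pd.DataFrame | None = None,
                 covariates: pd.DataFrame | None = None,
                 rho_cutoff: float = 0.4):
    """Mature/alternate-arm correlation table and arm-difference QTL scan.

    ``mature_expr`` and ``star_expr`` are row-aligned (same miRNA order) log
    expression matrices.  Returns ``(correlations, qtl_table)``; the QTL
    table is None unless genotype inputs are provided.
    """
    rows = []
    diffs = {}
    for rna in mature_expr.index:
        if rna not in star_expr.index:
            continue
        x = mature_expr.loc[rna].to_numpy(dtype=float)
        y = star_expr.loc[rna].to_numpy(dtype=float)
        if np.allclose(x, 0) or np.allclose(y, 0):
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((rna, float(rho), float(p), abs(rho) > rho_cutoff))
        diffs[rna] = x - y
    corr = pd.DataFrame(rows, columns=["feature", "rho", "p", "significant"])
    qtl = None
    if genotypes is not None and snp_info is not None and annotations is not None:
        diff_expr = pd.DataFrame(diffs, index=mature_expr.columns).T
        qtl = cis_eqtl_scan(diff_expr, genotypes, snp_info, annotations,
                            covariates)
    return corr, qtl
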