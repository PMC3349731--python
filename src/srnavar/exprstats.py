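"""Cross-tissue specificity, conservation-expression contingency tests,
cluster co-expression enrichment and miRNA-target correlation summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import encode_covariates, qvalues


def residualise(matrix: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each row by its OLS residuals on the encoded covariates.

    Library batch and multiplexing tag (categoricals) are one-hot encoded;
    the intercept removes row means.
    """
    X = encode_covariates(covariates, index=matrix.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    Y = matrix.to_numpy(dtype=float).T            # samples x rnas
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid.T, index=matrix.index, columns=matrix.columns)


def tissue_specificity(adipose: pd.DataFrame, others: dict[str, pd.DataFrame],
                       q_cut: float = 0.1, require_all: bool = True
                       ) -> pd.DataFrame:
    """Welch Z-tests of adipose mean log expression against other tissues.

    Summaries are per-RNA frames with columns ``mean``, ``var``, ``n``.
    ``Z = (mu_a - mu_t) / sqrt(var_a/n_a + var_t/n_t)``, two-tailed normal p,
    q across RNAs per tissue.  An RNA is flagged adipose-specific when Z > 0
    and q < ``q_cut`` against every other tissue (or, with
    ``require_all=False``, when the mean q across tissues is < ``q_cut``).
    """
    rows = []
    for tissue, summ in others.items():
        common = adipose.index.intersection(summ.index)
        mu_a = adipose.loc[common, "mean"]
        mu_t = summ.loc[common, "mean"]
        se = np.sqrt(adipose.loc[common, "var"] / adipose.loc[common, "n"]
                     + summ.loc[common, "var"] / summ.loc[common, "n"])
        valid = se > 0
        z = (mu_a - mu_t)[valid] / se[valid]
        p = 2 * stats.norm.sf(np.abs(z))
        q = qvalues(p)
        for rna, zi, pi, qi in zip(z.index, z, p, q):
            rows.append((rna, tissue, float(zi), float(pi), float(qi)))
    table = pd.DataFrame(rows, columns=["rna_id", "tissue", "z", "p", "q"])
    flags = []
    for rna, grp in table.groupby("rna_id"):
        if require_all:
            specific = bool(((grp["z"] > 0) & (grp["q"] < q_cut)).all()
                            and len(grp) == len(others))
        else:
            specific = bool((grp["z"] > 0).all() and grp["q"].mean() < q_cut)
        flags.append((rna, specific))
    flag = pd.DataFrame(flags, columns=["rna_id", "adipose_specific"])
    return table.merge(flag, on="rna_id")


def conservation_expression_test(expr_summary: pd.DataFrame,
                                 conservation: pd.Series,
                                 expr_cut: float = 10.0,
                                 cons_cut: float = 0.0,
                                 var_cut: float = 5.0):
    """Chi-squared (1 df) tests for depletion of highly expressed (and highly
    variable) unconserved genes.

    ``expr_summary`` has per-RNA ``mean`` and ``var`` of log expression.
    Returns a dict with the mean-based and variance-based 2x2 test results.
    """
    cons = conservation.reindex(expr_summary.index)
    if cons.isna().any():
        raise ValueError("every RNA needs a conservation score")
    out = {}
    for label, values, cut in (("mean", expr_summary["mean"], expr_cut),
                               ("var", expr_summary["var"], var_cut)):
        high = values > cut
        uncons = cons < cons_cut
        table = np.array([
            [int((high & uncons).sum()), int((high & ~uncons).sum())],
            [int((~high & uncons).sum()), int((~high & ~uncons).sum())],
        ], dtype=float)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError(f"degenerate margin in the {label}-based table")
        expected = (table.sum(axis=1, keepdims=True)
                    * table.sum(axis=0, keepdims=True) / table.sum())
        stat = float(((table - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(stat, df=1))
        out[label] = {"stat": stat, "p": p, "table": table}
    return out


def _median_pairwise_r(block: np.ndarray) -> float:
    r = np.corrcoef(block)
    iu = np.triu_indices_from(r, k=1)
    return float(np.median(r[iu]))


def cluster_correlation_enrichment(expr: pd.DataFrame,
                                   clusters: dict[str, list[str]],
                                   n_random: int = 1000,
                                   seed: int = 0,
                                   covariates: pd.DataFrame | None = None):
    """Cluster co-expression against size-matched random miRNA sets.

    Per cluster with >=2 expressed members, the median pairwise Pearson r
    (on covariate-residualised expression) is computed; cluster medians are
    compared to medians of ``n_random`` random same-size sets by a two-sided
    Mann-Whitney U test.  Returns (median of cluster medians, median of
    random medians, p).
    """
    if covariates is not None:
        expr = residualise(expr, covariates)
    rng = np.random.default_rng(seed)
    mat = expr.to_numpy(dtype=float)
    idx = {r: i for i, r in enumerate(expr.index)}
    cluster_meds, sizes = [], []
    for members in clusters.values():
        present = [idx[m] for m in members if m in idx]
        if len(present) < 2:
            continue
        cluster_meds.append(_median_pairwise_r(mat[present]))
        sizes.append(len(present))
    if len(cluster_meds) < 2:
        raise ValueError("need at least two clusters with two expressed members")
    random_meds = []
    for _ in range(n_random):
        size = sizes[rng.integers(len(sizes))]
        pick = rng.choice(len(expr), size=size, replace=False)
        random_meds.append(_median_pairwise_r(mat[pick]))
    u_p = stats.mannwhitneyu(cluster_meds, random_meds,
                             alternative="two-sided").pvalue
    return (float(np.median(cluster_meds)), float(np.median(random_meds)),
            float(u_p))


def target_correlation_summary(mirna_expr: pd.DataFrame,
                               mrna_expr: pd.DataFrame,
                               target_pairs: list[tuple[str, str]],
                               background_pairs: list[tuple[str, str]],
                               covariates: pd.DataFrame | None = None):
    """Mean miRNA-target correlation, one-sample t-test against zero, and a
    Mann-Whitney comparison with random pairs.

    Pearson r is computed per pair on covariate-residualised data (sample
    covariates subtracted by linear fit).
    """
    if not target_pairs:
        raise ValueError("empty target pair list")
    if covariates is not None:
        mirna_expr = residualise(mirna_expr, covariates)
        mrna_expr = residualise(mrna_expr, covariates)

    def pair_r(pairs):
        out = []
        for mir, probe in pairs:
            if mir not in mirna_expr.index or probe not in mrna_expr.index:
                continue
            x = mirna_expr.loc[mir].to_numpy(dtype=float)
            y = mrna_expr.loc[probe].to_numpy(dtype=float)
            out.append(float(np.corrcoef(x, y)[0, 1]))
        return np.asarray(out)

    r_t = pair_r(target_pairs)
    r_b = pair_r(background_pairs)
    t_p = float(stats.ttest_1samp(r_t, 0.0).pvalue)
    mw_p = (float(stats.mannwhitneyu(r_t, r_b, alternative="two-sided").pvalue)
            if len(r_b) else float("nan"))
    return {"mean_r": float(r_t.mean()), "t_p": t_p,
            "mannwhitney_p": mw_p, "n_pairs": int(len(r_t))}
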