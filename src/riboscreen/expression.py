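"""Relative quantification (qPCR) and count-based differential expression.

qPCR fold changes use the 2^-ddCt method with dual reference genes
(groEL and gyrA by default): per sample, dCt = Ct(target) - mean Ct of
the references; ddCt contrasts the test-group mean against a calibrator
group; the fold change is 2^-ddCt with an SD propagated from the
replicate dCt spread.

The count stage is a deliberately transparent re-implementation of the
usual RNA-seq workflow: median-of-ratios size factors, log2 fold
changes of normalized group means (+0.5 pseudocount), a Wald-style
two-sample test on log2 normalized counts whose per-gene variance is
stabilized with a method-of-moments negative-binomial dispersion pooled
across genes, Benjamini-Hochberg adjustment, and the significance rule
FDR < 0.05 together with log2FC > 3 for up-regulated calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "FoldChange",
    "ddct_fold_change",
    "size_factors",
    "dge_test",
    "bh_adjust",
    "welch_t_test",
]

DEFAULT_REFERENCE_GENES = ("groEL", "gyrA")

CT_COLUMNS = ("sample", "group", "gene", "ct")

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FoldChange:
    """A 2^-ddCt estimate with its propagated uncertainty."""

    fold: float
    sd: float
    ddct: float
    dct_test_mean: float
    dct_calibrator_mean: float
    n_test: int
    n_calibrator: int


def _sample_dct(
    table: pd.DataFrame, target_gene: str, reference_genes: tuple[str, ...]
) -> pd.DataFrame:
    for col in CT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"Ct table lacks required column {col!r}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    rows = []
    for (sample, group), sub in table.groupby(["sample", "group"], sort=True):
        genes = sub.groupby("gene")["ct"].mean()  # average technical replicates
        if target_gene not in genes:
            raise ValueError(f"sample {sample!r} lacks target gene {target_gene!r}")
        missing = [g for g in reference_genes if g not in genes]
        if missing:
            raise ValueError(f"sample {sample!r} lacks reference gene(s) {missing}")
        ref_ct = float(np.mean([genes[g] for g in reference_genes]))
        rows.append((sample, group, float(genes[target_gene]) - ref_ct))
    return pd.DataFrame(rows, columns=["sample", "group", "dct"])


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    calibrator_group: str = "WT",
    test_group: str | None = None,
) -> FoldChange:
    """Relative expression of ``target_gene`` by the 2^-ddCt method.

    ``ct_table`` needs columns sample, group, gene, ct (technical
    replicates as extra rows). ``test_group`` defaults to the one group
    that is not the calibrator. The SD combines the replicate dCt
    spreads of both groups on the fold-change scale (delta method).
    """
    dct = _sample_dct(ct_table, target_gene, tuple(reference_genes))
    groups = sorted(dct["group"].unique())
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    if test_group is None:
        others = [g for g in groups if g != calibrator_group]
        if len(others) != 1:
            raise ValueError(
                f"ambiguous test group among {others}; pass test_group explicitly"
            )
        test_group = others[0]
    if test_group not in groups:
        raise ValueError(f"test group {test_group!r} has no samples")
    test = dct.loc[dct["group"] == test_group, "dct"].to_numpy()
    cal = dct.loc[dct["group"] == calibrator_group, "dct"].to_numpy()
    ddct = float(test.mean() - cal.mean())
    fold = 2.0**-ddct
    var = 0.0
    if len(test) > 1:
        var += test.var(ddof=1) / len(test)
    if len(cal) > 1:
        var += cal.var(ddof=1) / len(cal)
    sd = fold * LN2 * math.sqrt(var)
    return FoldChange(
        fold=fold,
        sd=sd,
        ddct=ddct,
        dct_test_mean=float(test.mean()),
        dct_calibrator_mean=float(cal.mean()),
        n_test=len(test),
        n_calibrator=len(cal),
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    factor_j = median over genes of count_gj / geometric mean of gene g
    across samples, restricted to genes with all-positive counts. When
    no such gene exists the factors fall back to relative library sizes
    (a warning is emitted).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logs = np.log(mat[positive])
        log_geomean = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - log_geomean, axis=0))
    else:
        import warnings

        warnings.warn(
            "no gene with positive counts in all samples; "
            "falling back to library-size factors",
            stacklevel=2,
        )
        lib = mat.sum(axis=0)
        if lib.sum() == 0:
            raise ValueError("count matrix is entirely zero")
        factors = lib / np.exp(np.mean(np.log(lib[lib > 0])))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided unequal-variance (Welch) t-test.

    Degenerate input with zero variance in both groups and equal means
    returns (0, 1) by convention rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def dge_test(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    *,
    test_group: str = "mutant",
    reference_group: str = "WT",
    fdr_threshold: float = 0.05,
    min_log2fc: float = 3.0,
    two_sided_fc: bool = False,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential expression of ``test_group`` versus ``reference_group``.

    ``counts`` is genes x samples; ``groups`` maps sample id to group
    label. All-zero genes are discarded before testing. Returns a
    DataFrame indexed by gene with columns baseMeanWT, baseMeanMut,
    log2FC, pvalue, FDR, significant. By default significance is the
    one-sided up-regulation rule (FDR below threshold and log2FC above
    ``min_log2fc``); ``two_sided_fc`` switches to |log2FC|.
    """
    groups = pd.Series(groups)
    for name in (test_group, reference_group):
        n = int((groups == name).sum())
        if n < 2:
            raise ValueError(
                f"group {name!r} has {n} sample(s); at least 2 are required"
            )
    cols_ref = [s for s in counts.columns if groups.get(s) == reference_group]
    cols_test = [s for s in counts.columns if groups.get(s) == test_group]
    counts = counts.loc[(counts[cols_ref + cols_test].sum(axis=1) > 0)]
    sf = size_factors(counts[cols_ref + cols_test])
    norm = counts[cols_ref + cols_test].div(sf, axis=1)
    ref = norm[cols_ref].to_numpy()
    tst = norm[cols_test].to_numpy()
    mean_ref = ref.mean(axis=1)
    mean_tst = tst.mean(axis=1)
    log2fc = np.log2((mean_tst + pseudocount) / (mean_ref + pseudocount))

    # method-of-moments common NB dispersion pooled across genes:
    # Var = mu + alpha * mu^2 on the normalized scale
    mus = np.concatenate([mean_ref, mean_tst])
    variances = np.concatenate([ref.var(axis=1, ddof=1), tst.var(axis=1, ddof=1)])
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = (variances - mus) / np.square(mus)
    alpha_g = alpha_g[np.isfinite(alpha_g) & (mus > 0)]
    alpha = float(np.median(np.clip(alpha_g, 0.0, None))) if alpha_g.size else 0.0

    y_ref = np.log2(ref + pseudocount)
    y_tst = np.log2(tst + pseudocount)

    def stabilized_var(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
        observed = y.var(axis=1, ddof=1)
        predicted = (alpha + 1.0 / np.maximum(mu, pseudocount)) / (LN2**2)
        return np.maximum(observed, predicted)

    v_ref = stabilized_var(y_ref, mean_ref) / ref.shape[1]
    v_tst = stabilized_var(y_tst, mean_tst) / tst.shape[1]
    se = np.sqrt(v_ref + v_tst)
    z = (y_tst.mean(axis=1) - y_ref.mean(axis=1)) / se
    # pooled-dispersion variance is estimated from all genes, so a
    # normal reference distribution (Wald test) is appropriate
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    fdr = bh_adjust(pvals)
    fc_pass = np.abs(log2fc) > min_log2fc if two_sided_fc else log2fc > min_log2fc
    result = pd.DataFrame(
        {
            "baseMeanWT": mean_ref,
            "baseMeanMut": mean_tst,
            "log2FC": log2fc,
            "pvalue": pvals,
            "FDR": fdr,
            "significant": (fdr < fdr_threshold) & fc_pass,
        },
        index=counts.index,
    )
    result.attrs["dispersion"] = alpha
    result.attrs["size_factors"] = sf
    return result
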