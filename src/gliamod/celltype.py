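"""Bulk vs pseudobulk expression integration and candidate ranking.

To establish which cell class cultured satellite glial cells (SGCs)
resemble, bulk RNA-seq profiles are compared against pseudobulk profiles
built by summing single-cell counts per major DRG cell class (glia,
neurons, immune, endothelial, erythrocytes, fibroblasts, mural).  Both
platforms are jointly normalized with the trimmed mean of M-values (TMM),
converted to log-CPM, restricted to shared highly variable genes, and
compared with Spearman correlation.  Secreted-protein candidates are then
ranked by absolute SGC expression and by SGC specificity (ratio of SGC
CPM to the highest-expressing non-SGC class).

The synthetic generator draws negative-binomial counts with planted
class markers and a bulk sample derived from one class (optionally
contaminated by a second), with truth labels for recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_CLASSES",
    "generate_synthetic_expression",
    "pseudobulk",
    "tmm_factors",
    "tmm_log_cpm",
    "hvg_shared",
    "similarity",
    "specificity_and_rank",
    "dct_fold_change",
]

DEFAULT_CLASSES = (
    "glia",
    "neurons",
    "immune",
    "endothelial",
    "erythrocytes",
    "fibroblasts",
    "mural",
)

LOG_CPM_PRIOR = 0.5
SPECIFICITY_EPS = 0.01  # CPM pseudocount for specificity ratios


# -- synthetic data ---------------------------------------------------------


def generate_synthetic_expression(
    n_genes: int = 2000,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    cells_per_class: int = 40,
    markers_per_class: int = 20,
    seed: int = 0,
    marker_log2_effect: float = 3.0,
    bulk_class: str = "glia",
    bulk_samples: int = 3,
    contamination: float = 0.1,
    contaminant_class: str = "fibroblasts",
    nb_dispersion: float = 0.3,
    cell_library_size: int = 5000,
    bulk_library_size: int = 200000,
):
    """Generate paired single-cell and bulk count matrices with truth labels.

    Returns ``(sc_counts, cell_classes, bulk_counts, markers)`` where
    ``sc_counts`` is a genes × cells DataFrame, ``cell_classes`` a Series
    of class labels per cell, ``bulk_counts`` a genes × samples DataFrame
    drawn from ``bulk_class`` with a ``contamination`` fraction of its
    expected profile taken from ``contaminant_class``, and ``markers``
    maps each class to its planted marker gene list.

    Counts are negative-binomial around class-specific expected profiles;
    markers are elevated 2**``marker_log2_effect``-fold in their class.
    """
    if markers_per_class * len(classes) > n_genes:
        raise ValueError("more markers requested than genes available")
    if bulk_class not in classes or contaminant_class not in classes:
        raise ValueError("bulk_class and contaminant_class must be in classes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]

    base = rng.lognormal(mean=1.0, sigma=1.2, size=n_genes)
    markers: dict[str, list[str]] = {}
    class_profiles: dict[str, np.ndarray] = {}
    idx = 0
    for cls in classes:
        prof = base.copy()
        mk = list(range(idx, idx + markers_per_class))
        prof[mk] *= 2.0**marker_log2_effect
        markers[cls] = [genes[i] for i in mk]
        class_profiles[cls] = prof / prof.sum()
        idx += markers_per_class

    def nb_draw(mean: np.ndarray) -> np.ndarray:
        # NB with var = mu + dispersion * mu^2
        r = 1.0 / nb_dispersion
        lam = rng.gamma(shape=r, scale=mean / r)
        return rng.poisson(lam)

    cols = {}
    labels = {}
    for cls in classes:
        mu = class_profiles[cls] * cell_library_size
        for c in range(cells_per_class):
            name = f"{cls}_{c + 1}"
            cols[name] = nb_draw(mu)
            labels[name] = cls
    sc = pd.DataFrame(cols, index=genes)
    cell_classes = pd.Series(labels, name="cell_class")

    bulk_profile = (1.0 - contamination) * class_profiles[bulk_class] + (
        contamination * class_profiles[contaminant_class]
    )
    bulk = pd.DataFrame(
        {
            f"bulk_{s + 1}": nb_draw(bulk_profile * bulk_library_size)
            for s in range(bulk_samples)
        },
        index=genes,
    )
    return sc, cell_classes, bulk, markers


# -- normalisation ----------------------------------------------------------


def pseudobulk(sc: pd.DataFrame, cell_classes: pd.Series) -> pd.DataFrame:
    """Aggregate single-cell counts by class and convert to CPM.

    Returns a genes × class DataFrame of CPM (every column sums to 1e6).
    """
    missing = [c for c in sc.columns if c not in cell_classes.index]
    if missing:
        raise ValueError(f"cells without class labels: {missing[:5]}")
    summed = sc.T.groupby(cell_classes.loc[sc.columns]).sum().T
    totals = summed.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"class(es) with zero total counts: {bad}")
    return summed / totals * 1e6


def log_cpm(cpm: pd.DataFrame, prior: float = LOG_CPM_PRIOR) -> pd.DataFrame:
    """log2(CPM + prior)."""
    return np.log2(cpm + prior)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """TMM normalization factors (geometric mean 1) for a count matrix.

    The reference sample is the one whose upper-quartile (of nonzero-
    scaled counts) is closest to the mean upper-quartile.  For every
    sample, gene-wise M (log-ratio) and A (log-abundance) values against
    the reference are double-trimmed (30% on M, 5% on A, two-sided) and
    the factor is 2 to the precision-weighted mean of the surviving M
    values.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"sample(s) with zero counts: {bad}")
    x = counts.to_numpy(dtype=float)
    frac = x / lib.to_numpy()
    uq = np.array([np.quantile(frac[:, j][x[:, j] > 0], 0.75) for j in range(x.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(x.shape[1])
    xr = x[:, ref_j]
    nr = lib.iloc[ref_j]
    for j in range(x.shape[1]):
        if j == ref_j:
            continue
        xj = x[:, j]
        nj = lib.iloc[j]
        keep = (xj > 0) & (xr > 0)
        if keep.sum() == 0:
            continue
        pj, pr = xj[keep] / nj, xr[keep] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # asymptotic (delta-method) variance of M
        w = (nj - xj[keep]) / (nj * xj[keep]) + (nr - xr[keep]) / (nr * xr[keep])
        lo_m, hi_m = np.quantile(m, [0.30, 0.70])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        trim = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if trim.sum() == 0 or w[trim].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(m[trim] / w[trim]) / np.sum(1.0 / w[trim]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_log_cpm(counts: pd.DataFrame, prior: float = LOG_CPM_PRIOR) -> pd.DataFrame:
    """Joint TMM normalization followed by log-CPM on effective sizes."""
    factors = tmm_factors(counts)
    eff = counts.sum(axis=0) * factors
    return np.log2(counts / eff * 1e6 + prior)


# -- comparison -------------------------------------------------------------


def hvg_shared(
    bulk_logcpm: pd.DataFrame, pseudo_logcpm: pd.DataFrame, n: int = 5000
) -> list[str]:
    """Top highly variable genes shared between the two platforms.

    Genes are ranked by log-CPM variance within each platform separately;
    the combined rank is the better (minimum) of the two, so a gene
    highly variable on either platform is favoured; ties break by gene
    name for determinism.  Returns min(n, overlap) genes.
    """
    shared = bulk_logcpm.index.intersection(pseudo_logcpm.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between platforms")
    var_b = bulk_logcpm.loc[shared].var(axis=1, ddof=1)
    var_p = pseudo_logcpm.loc[shared].var(axis=1, ddof=1)
    rank_b = var_b.rank(ascending=False, method="min")
    rank_p = var_p.rank(ascending=False, method="min")
    combined = pd.DataFrame(
        {"rank": np.minimum(rank_b, rank_p).to_numpy(), "gene": list(shared)}
    ).sort_values(["rank", "gene"], kind="mergesort")
    return combined["gene"].head(min(n, len(shared))).tolist()


def similarity(
    bulk_logcpm: pd.DataFrame | pd.Series,
    pseudo_logcpm: pd.DataFrame,
    genes: list[str],
) -> pd.Series:
    """Spearman correlation of the bulk profile with each class column.

    ``bulk_logcpm`` may hold several samples; they are averaged into one
    profile first.  Ties are mid-ranked (the Spearman default).
    """
    if len(genes) < 3:
        raise ValueError("at least 3 genes required for a rank correlation")
    if isinstance(bulk_logcpm, pd.DataFrame):
        bulk = bulk_logcpm.mean(axis=1)
    else:
        bulk = bulk_logcpm
    missing = [g for g in genes if g not in bulk.index or g not in pseudo_logcpm.index]
    if missing:
        raise ValueError(f"genes absent from a profile: {missing[:5]}")
    b = bulk.loc[genes]
    out = {}
    for cls in pseudo_logcpm.columns:
        rho = stats.spearmanr(b, pseudo_logcpm.loc[genes, cls]).statistic
        out[cls] = float(rho)
    return pd.Series(out, name="spearman_rho")


def specificity_and_rank(
    candidate_genes: list[str],
    pseudo_cpm: pd.DataFrame,
    sgc_class: str = "glia",
) -> pd.DataFrame:
    """Rank candidates by SGC expression and SGC specificity.

    Specificity is SGC CPM over the maximum non-SGC CPM (pseudocount
    0.01 CPM keeps genes absent elsewhere finite).  Two descending rank
    columns (expression, specificity) are combined by their mean; ties
    break by specificity ratio then gene symbol.
    """
    if sgc_class not in pseudo_cpm.columns:
        raise ValueError(f"no {sgc_class!r} class in the pseudobulk profile")
    missing = [g for g in candidate_genes if g not in pseudo_cpm.index]
    if missing:
        raise ValueError(f"candidates absent from profile: {missing[:5]}")
    sub = pseudo_cpm.loc[candidate_genes]
    sgc = sub[sgc_class]
    others = sub.drop(columns=[sgc_class])
    max_other = others.max(axis=1)
    ratio = sgc / np.maximum(max_other, SPECIFICITY_EPS)
    rank_expr = sgc.rank(ascending=False, method="min")
    rank_spec = ratio.rank(ascending=False, method="min")
    combined = (rank_expr + rank_spec) / 2.0
    out = pd.DataFrame(
        {
            "gene": candidate_genes,
            "sgc_cpm": sgc.to_numpy(),
            "max_other_cpm": max_other.to_numpy(),
            "specificity_ratio": ratio.to_numpy(),
            "rank_expression": rank_expr.to_numpy(),
            "rank_specificity": rank_spec.to_numpy(),
            "combined_rank": combined.to_numpy(),
        }
    )
    return out.sort_values(
        ["combined_rank", "specificity_ratio", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


# -- qPCR -------------------------------------------------------------------


def dct_fold_change(
    ct: pd.DataFrame, housekeeping_gene: str, reference_condition: str | None = None
) -> pd.DataFrame:
    """Relative expression by the ΔCT method and condition fold changes.

    ``ct`` needs columns (gene, sample, condition, Ct).  Per sample,
    ΔCT = Ct_gene − Ct_housekeeping and relative expression is
    2**(−ΔCT); the fold change of each condition is the ratio of its
    mean relative expression to the reference condition's (the first
    condition in sorted order unless given).
    """
    required = {"gene", "sample", "condition", "Ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    hk = ct[ct["gene"] == housekeeping_gene].set_index("sample")["Ct"]
    samples = ct["sample"].unique()
    missing = [s for s in samples if s not in hk.index]
    if missing:
        raise ValueError(f"housekeeping Ct missing for sample(s): {missing}")
    df = ct[ct["gene"] != housekeeping_gene].copy()
    df["dct"] = df["Ct"] - df["sample"].map(hk)
    df["rel_expr"] = 2.0 ** (-df["dct"])
    means = df.groupby(["gene", "condition"])["rel_expr"].mean().unstack()
    if reference_condition is None:
        reference_condition = sorted(means.columns)[0]
    if reference_condition not in means.columns:
        raise ValueError(f"unknown reference condition {reference_condition!r}")
    fc = means.div(means[reference_condition], axis=0)
    fc.columns = [f"fold_change_{c}" for c in fc.columns]
    out = means.copy()
    out.columns = [f"mean_rel_expr_{c}" for c in out.columns]
    return pd.concat([out, fc], axis=1).reset_index()
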