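"""Secretome filtering, matrisome classification and enrichment statistics.

Mass-spectrometry quantification of conditioned media (CM) against a
media-only negative control identifies secreted proteins: a protein is a
high-confidence candidate when it is significantly elevated in CM
(Welch test on log2 intensities, p below threshold), at least two-fold
enriched, and shows minimal signal in the negative controls.  Candidate
sets are then classified against a user-supplied matrisome category map
and tested for annotation enrichment with the hypergeometric distribution
and Benjamini–Hochberg FDR control.

A seeded log-normal generator emulates the structure of such experiments
(a spiked secreted subset, background proteins shared with the media)
and returns ground-truth labels for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SecretomeFilters",
    "EnrichmentResult",
    "generate_synthetic_secretome",
    "cm_specific_proteins",
    "high_confidence_candidates",
    "matrisome_classify",
    "enrichment",
    "MATRISOME_CATEGORIES",
]

GROUPS = ("CM", "pellet", "media_control")

MATRISOME_CATEGORIES = (
    "collagens",
    "ECM glycoproteins",
    "proteoglycans",
    "ECM regulators",
    "ECM-affiliated",
    "secreted factors",
    "non-matrisome",
)


@dataclass(frozen=True)
class SecretomeFilters:
    """Thresholds for calling high-confidence secreted proteins.

    ``control_max_fraction`` bounds the mean control/CM intensity ratio
    and ``control_detect_max`` the number of control replicates with
    nonzero signal — together the operational reading of "minimal signal
    in negative controls".  The fold-change comparison is inclusive
    (fc >= fc_min).
    """

    p_max: float = 0.05
    fc_min: float = 2.0
    control_max_fraction: float = 0.1
    control_detect_max: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one annotation term."""

    term: str
    hits_in_set: int
    set_size: int
    hits_in_universe: int
    universe_size: int
    p: float
    fdr: float


def _intensity_columns(q: pd.DataFrame, group: str) -> list[str]:
    cols = [c for c in q.columns if c.startswith(f"{group}_")]
    if not cols:
        raise ValueError(f"no intensity columns for group {group!r} (expected '{group}_<i>')")
    return cols


def generate_synthetic_secretome(
    n_proteins: int = 740,
    n_secreted: int = 73,
    n_replicates: int = 3,
    effect_log2fc: float = 3.0,
    noise_sd_log: float = 0.5,
    seed: int = 0,
    control_detect_prob: float = 0.0,
) -> tuple[pd.DataFrame, set[str]]:
    """Generate a protein quantification table with known secreted truth.

    Intensities are log-normal (log2 scale, per-protein base level drawn
    from N(16, 2), replicate noise sd ``noise_sd_log``).  The first
    ``n_secreted`` proteins are truly secreted: elevated in CM by
    ``effect_log2fc`` and absent from the media control (each control
    replicate detects them with probability ``control_detect_prob``).
    Background proteins appear identically in CM and media control
    (media-derived contaminants); all proteins appear in the cell pellet.
    Returns the table and the set of true secreted protein ids.
    """
    if n_secreted > n_proteins:
        raise ValueError("n_secreted cannot exceed n_proteins")
    if n_replicates < 2:
        raise ValueError("at least 2 replicates per group required")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    genes = [f"Gene{i}" for i in range(n_proteins)]
    base = rng.normal(16.0, 2.0, size=n_proteins)
    secreted = np.zeros(n_proteins, dtype=bool)
    secreted[:n_secreted] = True

    data: dict[str, np.ndarray] = {}
    for r in range(n_replicates):
        cm = base + rng.normal(0.0, noise_sd_log, size=n_proteins)
        cm[secreted] += effect_log2fc
        data[f"CM_{r + 1}"] = 2.0**cm
    for r in range(n_replicates):
        pellet = base + rng.normal(0.0, noise_sd_log, size=n_proteins)
        data[f"pellet_{r + 1}"] = 2.0**pellet
    for r in range(n_replicates):
        ctl = base + rng.normal(0.0, noise_sd_log, size=n_proteins)
        vals = 2.0**ctl
        detected = rng.random(n_proteins) < control_detect_prob
        vals[secreted & ~detected] = 0.0
        data[f"media_control_{r + 1}"] = vals

    q = pd.DataFrame({"protein": proteins, "gene": genes, **data})
    return q, set(np.array(proteins)[secreted])


def cm_specific_proteins(q: pd.DataFrame, control_detect_max: int = 0) -> set[str]:
    """Proteins detected in CM but (essentially) absent from media control.

    Detection is nonzero intensity; a protein qualifies when detected in
    at least one CM replicate and in at most ``control_detect_max`` media
    control replicates.
    """
    cm_cols = _intensity_columns(q, "CM")
    ctl_cols = _intensity_columns(q, "media_control")
    cm_detected = (q[cm_cols] > 0).sum(axis=1) >= 1
    ctl_detected = (q[ctl_cols] > 0).sum(axis=1) <= control_detect_max
    return set(q.loc[cm_detected & ctl_detected, "protein"])


def high_confidence_candidates(
    q: pd.DataFrame, filters: SecretomeFilters | None = None
) -> pd.DataFrame:
    """Score every protein against the high-confidence secretion filters.

    Per protein: Welch two-sample t-test on log2(intensity + 1) between
    CM and media control; fold change as the ratio of raw group means
    with pseudo-count 1.  ``pass`` requires p < p_max, fc >= fc_min, and
    the negative-control criteria.  Returns a table with one row per
    protein (protein, gene, log2fc, p, pass_filter) sorted by p.
    """
    if filters is None:
        filters = SecretomeFilters()
    cm_cols = _intensity_columns(q, "CM")
    ctl_cols = _intensity_columns(q, "media_control")
    if len(cm_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError("at least 2 replicates required in CM and media_control")

    cm = q[cm_cols].to_numpy(dtype=float)
    ctl = q[ctl_cols].to_numpy(dtype=float)
    log_cm = np.log2(cm + 1.0)
    log_ctl = np.log2(ctl + 1.0)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical groups trigger a harmless precision warning; the
        # resulting NaN p-values are mapped to 1 (no evidence) below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(log_cm, log_ctl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)

    cm_mean = cm.mean(axis=1)
    ctl_mean = ctl.mean(axis=1)
    fc = (cm_mean + 1.0) / (ctl_mean + 1.0)
    ctl_detect = (ctl > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ctl_frac = np.where(cm_mean > 0, ctl_mean / cm_mean, np.inf)

    passed = (
        (p < filters.p_max)
        & (fc >= filters.fc_min)
        & (ctl_detect <= filters.control_detect_max)
        & (ctl_frac <= filters.control_max_fraction)
    )
    out = pd.DataFrame(
        {
            "protein": q["protein"],
            "gene": q["gene"],
            "log2fc": np.log2(fc),
            "p": p,
            "pass_filter": passed,
        }
    )
    return out.sort_values(["p", "protein"], kind="mergesort").reset_index(drop=True)


def matrisome_classify(
    genes: list[str] | pd.Series, category_map: pd.DataFrame
) -> pd.Series:
    """Assign each gene symbol a matrisome category.

    ``category_map`` is a two-column table (gene, category); lookup is
    case-insensitive and unmapped genes fall into ``non-matrisome``.
    Conflicting duplicate map entries raise.
    """
    if not {"gene", "category"}.issubset(category_map.columns):
        raise ValueError("category_map needs columns 'gene' and 'category'")
    cm = category_map.assign(_key=category_map["gene"].str.upper())
    conflicts = cm.groupby("_key")["category"].nunique()
    if (conflicts > 1).any():
        dupes = conflicts[conflicts > 1].index.tolist()
        raise ValueError(f"conflicting duplicate map entries for: {', '.join(dupes)}")
    lookup = dict(zip(cm["_key"], cm["category"]))
    genes = pd.Series(genes, dtype=str)
    return pd.Series(
        [lookup.get(g.upper(), "non-matrisome") for g in genes],
        index=genes.index,
        name="category",
    )


def enrichment(
    hit_set: set[str],
    universe: set[str],
    annotation: dict[str, set[str]],
    fdr_cutoff: float = 0.5,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms.

    For each term, the upper-tail probability of observing at least the
    realised overlap between ``hit_set`` and the term's genes when
    drawing ``len(hit_set)`` genes from ``universe`` without replacement;
    p-values are BH-adjusted across all tested terms, and terms passing
    ``fdr < fdr_cutoff`` are returned sorted by p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hit_set <= universe:
        raise ValueError("hit_set must be a subset of the universe")
    n_univ = len(universe)
    n_hits = len(hit_set)
    results = []
    for term in sorted(annotation):
        term_genes = annotation[term] & universe
        k = len(term_genes & hit_set)
        m = len(term_genes)
        # P(X >= k) for X ~ Hypergeom(N=n_univ, K=m, n=n_hits)
        p = float(stats.hypergeom.sf(k - 1, n_univ, m, n_hits))
        results.append(
            EnrichmentResult(
                term=term,
                hits_in_set=k,
                set_size=m,
                hits_in_universe=n_hits,
                universe_size=n_univ,
                p=min(p, 1.0),
                fdr=np.nan,
            )
        )
    if not results:
        return []
    _, fdrs, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    kept = [r for r in results if r.fdr < fdr_cutoff]
    return sorted(kept, key=lambda r: (r.p, r.term))
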