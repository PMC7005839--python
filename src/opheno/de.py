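"""Minimal negative-binomial differential-expression stage for bulk counts.

Implements the classic count-based pipeline on a genes x samples integer
matrix: median-of-ratios size factors, per-gene method-of-moments dispersion
(no information sharing across genes), an exact conditional negative-binomial
test of the two condition sums, Benjamini-Hochberg adjustment, the published
selection filter (|fold change| > 1.5, p < 0.01, mean normalized counts > 40
in either condition) and a top-variance PCA of the samples.  Exact numerical
parity with any particular DE package is a non-goal; the procedure itself is
the contract.

The modelling surface is a statsmodels-style pair: :class:`NBDifferential`
holds the data, ``fit()`` returns :class:`DEResults` with the per-gene table,
the filter and the volcano/PCA helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "simulate_counts",
    "estimate_size_factors",
    "nb_exact_test",
    "nb_differential_test",
    "apply_de_filters",
    "top_variance_pca",
    "NBDifferential",
    "DEResults",
]


@dataclass
class CountMatrix:
    """Genes x samples nonnegative integer counts with condition labels."""

    counts: pd.DataFrame  # index: gene ids; columns: sample ids
    conditions: pd.Series  # per-sample condition label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            raise ValueError("every sample needs a condition label")

    @property
    def condition_names(self) -> list[str]:
        return list(pd.unique(self.conditions))


def simulate_counts(
    n_genes: int = 2000,
    n_per_group: int = 5,
    planted: Mapping[int, float] | None = None,
    dispersion: float = 0.05,
    depth_factors: Sequence[float] | None = None,
    base_mean: float | Sequence[float] = 100.0,
    base_mean_sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
    condition_names: tuple[str, str] = ("non_addicted", "addicted"),
) -> CountMatrix:
    """Negative-binomial count matrix with planted fold changes.

    ``planted`` maps gene index -> fold change applied to the second
    condition.  Per-gene base means are lognormal around ``base_mean`` unless
    an explicit array is given.  ``depth_factors`` multiply per-sample means
    (default all 1).  Variance follows mu + dispersion * mu^2; dispersion 0
    gives Poisson counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    if depth_factors is None:
        depth = np.ones(n_samples)
    else:
        depth = np.asarray(depth_factors, dtype=float)
        if depth.size != n_samples or np.any(depth <= 0):
            raise ValueError("need one positive depth factor per sample")
    if np.isscalar(base_mean):
        means = float(base_mean) * np.exp(
            rng.normal(-0.5 * base_mean_sigma**2, base_mean_sigma, size=n_genes)
        )
    else:
        means = np.asarray(base_mean, dtype=float)
        if means.size != n_genes:
            raise ValueError("base_mean array must have n_genes entries")
    fc = np.ones(n_genes)
    for g, f in (planted or {}).items():
        if f <= 0:
            raise ValueError("planted fold changes must be positive")
        fc[g] = f
    # genes x samples mean matrix
    group2 = np.zeros(n_samples, dtype=bool)
    group2[n_per_group:] = True
    mu = means[:, None] * depth[None, :]
    mu[:, group2] *= fc[:, None]
    if dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    samples = [
        f"{condition_names[0]}_{i + 1}" for i in range(n_per_group)
    ] + [f"{condition_names[1]}_{i + 1}" for i in range(n_per_group)]
    conditions = pd.Series(
        [condition_names[0]] * n_per_group + [condition_names[1]] * n_per_group,
        index=samples,
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), conditions)


def estimate_size_factors(
    counts: pd.DataFrame | np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """Median-of-ratios sample normalization factors.

    For each gene with all-positive counts, the ratio of each sample's count
    to the gene's geometric mean is formed; the per-sample factor is the
    median of those ratios, rescaled so the factors' geometric mean is 1.
    """
    k = np.asarray(counts, dtype=float) + pseudocount
    positive = np.all(k > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "pass pseudocount > 0 to proceed"
        )
    logs = np.log(k[positive])
    log_gmean = logs.mean(axis=1, keepdims=True)
    log_factors = np.median(logs - log_gmean, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean -> 1
    return np.exp(log_factors)


def _nbinom_params(mean: float, var: float) -> tuple[float, float]:
    """scipy nbinom (r, p) from mean/variance; requires var > mean."""
    r = mean**2 / (var - mean)
    return r, r / (r + mean)


def _logpmf_rows(
    x: np.ndarray, means: np.ndarray, variances: np.ndarray
) -> np.ndarray:
    """Row-wise count log-pmf over ``x`` for several (mean, variance) pairs;
    NB where var > mean, Poisson otherwise."""
    out = np.empty((means.size, x.size))
    over = variances > means * (1 + 1e-8)
    if over.any():
        r = means[over] ** 2 / (variances[over] - means[over])
        p = r / (r + means[over])
        out[over] = sps.nbinom.logpmf(x[None, :], r[:, None], p[:, None])
    if (~over).any():
        out[~over] = sps.poisson.logpmf(x[None, :], means[~over][:, None])
    return out


def nb_exact_test(
    k_a: int,
    k_b: int,
    mean_a: float | np.ndarray,
    mean_b: float | np.ndarray,
    var_a: float | np.ndarray,
    var_b: float | np.ndarray,
) -> float:
    """Exact conditional two-sided p-value for two negative-binomial sums.

    Conditions on the total ``k_a + k_b`` and sums the probabilities of all
    splits at most as likely as the observed one, each condition sum modelled
    as NB with the given mean and variance (Poisson if var <= mean).  When
    the mean/variance arguments are arrays (one entry per variance-quadrature
    node, see :func:`nb_differential_test`), the returned p-value is the
    average over nodes.
    """
    total = int(k_a + k_b)
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    mean_a = np.atleast_1d(np.asarray(mean_a, dtype=float))
    mean_b = np.atleast_1d(np.asarray(mean_b, dtype=float))
    var_a = np.atleast_1d(np.asarray(var_a, dtype=float))
    var_b = np.atleast_1d(np.asarray(var_b, dtype=float))
    lp = _logpmf_rows(a, mean_a, var_a) + _logpmf_rows(a, mean_b, var_b)[:, ::-1]
    lp -= lp.max(axis=1, keepdims=True)
    p_all = np.exp(lp)
    p_obs = p_all[:, int(k_a)]
    # tolerance guards against ties broken by rounding
    keep = p_all <= p_obs[:, None] * (1 + 1e-10)
    p_nodes = np.minimum(
        1.0, (p_all * keep).sum(axis=1) / p_all.sum(axis=1)
    )
    return float(p_nodes.mean())


def nb_differential_test(
    counts: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    size_factors: Sequence[float] | None = None,
    dispersion_floor: float = 1e-8,
    reference: str | None = None,
    variance_quadrature: int = 16,
) -> pd.DataFrame:
    """Per-gene negative-binomial differential test between two conditions.

    Dispersion is estimated per gene by method of moments on normalized
    counts, pooled across the two conditions (no sharing across genes), with
    a small floor.  The p-value is the exact conditional test of the two raw
    condition sums, averaged over the sampling uncertainty of the per-gene
    variance estimate: the pooled variance is treated as scaled
    inverse-chi-square with ``n - 2`` degrees of freedom and the test is
    evaluated at ``variance_quadrature`` fixed mid-point quantiles of that
    distribution (deterministic; set to 1 for the plain plug-in test).
    Without this averaging the plug-in test is anticonservative at small n,
    because genes whose dispersion happens to be underestimated dominate the
    extreme tail.  Fold change is the ratio of normalized condition means
    (second condition over reference).  BH-adjusted p-values are included.
    All-zero genes get p = 1 and an ``all_zero`` flag.
    """
    counts_df = (
        counts if isinstance(counts, pd.DataFrame)
        else pd.DataFrame(np.asarray(counts))
    )
    k = counts_df.to_numpy(dtype=float)
    labels = pd.Series(list(labels), index=counts_df.columns)
    names = list(pd.unique(labels))
    if len(names) != 2:
        raise ValueError("exactly two conditions are required")
    if reference is not None:
        if reference not in names:
            raise ValueError(f"reference {reference!r} not among conditions")
        names = [reference, next(c for c in names if c != reference)]
    mask_a = (labels == names[0]).to_numpy()
    mask_b = (labels == names[1]).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 samples per condition")
    if size_factors is None:
        size_factors = estimate_size_factors(k)
    s = np.asarray(size_factors, dtype=float)
    x = k / s[None, :]  # normalized counts

    q_all = x.mean(axis=1)
    q_a = x[:, mask_a].mean(axis=1)
    q_b = x[:, mask_b].mean(axis=1)
    # pooled within-condition variance of normalized counts
    resid = np.concatenate(
        [x[:, mask_a] - q_a[:, None], x[:, mask_b] - q_b[:, None]], axis=1
    )
    df_resid = n_a + n_b - 2
    v = (resid**2).sum(axis=1) / df_resid
    shot = q_all * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(q_all > 0, (v - shot) / q_all**2, 0.0)
    alpha = np.maximum(alpha, dispersion_floor)

    s_a, s_b = s[mask_a], s[mask_b]
    sum_a = k[:, mask_a].sum(axis=1)
    sum_b = k[:, mask_b].sum(axis=1)
    mean_a = q_all * s_a.sum()
    mean_b = q_all * s_b.sum()

    # variance-uncertainty quadrature: v_node = v * df / chi2-quantile
    m = max(1, int(variance_quadrature))
    chi_nodes = sps.chi2.ppf((np.arange(m) + 0.5) / m, df_resid)
    n_genes = k.shape[0]
    pvals = np.ones(n_genes)
    all_zero = q_all == 0
    for g in range(n_genes):
        if all_zero[g]:
            continue
        v_nodes = v[g] * df_resid / chi_nodes
        alpha_g = np.maximum((v_nodes - shot[g]) / q_all[g] ** 2,
                             dispersion_floor)
        pvals[g] = nb_exact_test(
            int(sum_a[g]), int(sum_b[g]),
            np.full(m, mean_a[g]), np.full(m, mean_b[g]),
            mean_a[g] + alpha_g * q_all[g] ** 2 * np.sum(s_a**2),
            mean_b[g] + alpha_g * q_all[g] ** 2 * np.sum(s_b**2),
        )
    padj = multipletests(pvals, method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(q_a > 0, q_b / q_a, np.inf)
        fc = np.where(q_b == 0, np.where(q_a > 0, 0.0, np.nan), fc)
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {
            "base_mean": q_all,
            "mean_a": q_a,
            "mean_b": q_b,
            "fold_change": fc,
            "log2_fold_change": log2fc,
            "dispersion": alpha,
            "p_value": pvals,
            "p_adj": padj,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "all_zero": all_zero,
        },
        index=counts_df.index,
    )


def apply_de_filters(
    result: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    min_mean: float = 40.0,
) -> tuple[list, list]:
    """Published selection filter: |FC| > 1.5 (either direction), raw
    p < 0.01, and mean normalized counts > 40 in either condition.  Returns
    (up-regulated genes, down-regulated genes)."""
    fc = result["fold_change"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        passed_fc_up = fc > fc_threshold
        passed_fc_down = fc < 1.0 / fc_threshold
    passed_p = result["p_value"].to_numpy() < p_threshold
    passed_mean = (
        (result["mean_a"].to_numpy() > min_mean)
        | (result["mean_b"].to_numpy() > min_mean)
    )
    up = result.index[passed_fc_up & passed_p & passed_mean]
    down = result.index[passed_fc_down & passed_p & passed_mean]
    return list(up), list(down)


def top_variance_pca(
    counts: pd.DataFrame,
    n_top: int = 500,
    size_factors: Sequence[float] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the samples on the top-variance genes of the normalized,
    log-transformed matrix.  Returns (coordinates, explained variances);
    deterministic up to component sign."""
    k = counts.to_numpy(dtype=float)
    if k.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if size_factors is None:
        size_factors = estimate_size_factors(k, pseudocount=0.5)
    x = np.log2(k / np.asarray(size_factors)[None, :] + 1.0)
    n_top_eff = min(n_top, x.shape[0])
    if n_top_eff < n_top:
        warnings.warn(
            f"n_top={n_top} exceeds the {x.shape[0]} available genes; using all",
            UserWarning,
        )
    order = np.argsort(x.var(axis=1))[::-1][:n_top_eff]
    sub = x[order].T  # samples x genes
    sub = sub - sub.mean(axis=0, keepdims=True)
    u, sing, _ = np.linalg.svd(sub, full_matrices=False)
    n_components = min(n_components, sing.size)
    coords = u[:, :n_components] * sing[:n_components]
    explained = sing[:n_components] ** 2 / max(1, sub.shape[0] - 1)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=counts.columns, columns=cols), explained


class NBDifferential:
    """Two-condition NB differential-expression model over a count matrix."""

    def __init__(
        self,
        counts: pd.DataFrame | CountMatrix,
        conditions: Sequence[str] | None = None,
        reference: str | None = None,
    ) -> None:
        if isinstance(counts, CountMatrix):
            self.counts = counts.counts
            self.conditions = counts.conditions
        else:
            if conditions is None:
                raise ValueError("conditions required with a raw count frame")
            self.counts = counts
            self.conditions = pd.Series(list(conditions), index=counts.columns)
        self.reference = reference

    def fit(self, dispersion_floor: float = 1e-8) -> "DEResults":
        size_factors = estimate_size_factors(self.counts)
        table = nb_differential_test(
            self.counts,
            self.conditions,
            size_factors=size_factors,
            dispersion_floor=dispersion_floor,
            reference=self.reference,
        )
        return DEResults(self, table, size_factors)


class DEResults:
    """Fitted per-gene table plus the filter, volcano and PCA views."""

    def __init__(self, model: NBDifferential, table: pd.DataFrame,
                 size_factors: np.ndarray) -> None:
        self.model = model
        self.table = table
        self.size_factors = pd.Series(size_factors, index=model.counts.columns,
                                      name="size_factor")

    def selected(self, fc_threshold: float = 1.5, p_threshold: float = 0.01,
                 min_mean: float = 40.0) -> tuple[list, list]:
        return apply_de_filters(self.table, fc_threshold, p_threshold, min_mean)

    def volcano_table(self, **filter_kwargs) -> pd.DataFrame:
        up, down = self.selected(**filter_kwargs)
        chosen = set(up) | set(down)
        with np.errstate(divide="ignore"):
            neglogp = -np.log10(np.maximum(self.table["p_value"], 1e-300))
        return pd.DataFrame(
            {
                "log2_fold_change": self.table["log2_fold_change"],
                "neg_log10_p": neglogp,
                "selected": [g in chosen for g in self.table.index],
            },
            index=self.table.index,
        )

    def pca(self, n_top: int = 500, n_components: int = 2):
        return top_variance_pca(self.model.counts, n_top=n_top,
                                size_factors=self.size_factors.to_numpy(),
                                n_components=n_components)

    def summary(self, fdr: float = 0.1) -> str:
        up, down = self.selected()
        n_sig_fdr = int((self.table["p_adj"] < fdr).sum())
        lines = [
            "Negative-binomial differential expression",
            "=" * 44,
            f"genes: {len(self.table)}   samples: {self.model.counts.shape[1]}",
            "size factors: "
            + ", ".join(f"{v:.3f}" for v in self.size_factors),
            f"selected (|FC|>1.5, p<0.01, mean>40): {len(up)} up, {len(down)} down",
            f"BH-adjusted p < {fdr:g}: {n_sig_fdr} genes",
        ]
        return "\n".join(lines)
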