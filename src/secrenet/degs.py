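"""Bulk RNA-seq differential expression between plasma-cell populations.

The transcriptomic arm of the prioritization funnel compares circulating
antibody-secreting cells (blood ASC) with bone-marrow long-lived plasma
cells (BM LLPC) from a gene-level count matrix:

1. TMM library-size normalization (trimmed mean of M-values),
2. log2 counts-per-million conversion with a small prior count,
3. a lower abundance threshold of 3 log2 units (chosen in the source
   study by plotting coefficient of variation against mean abundance),
4. principal-component variance analysis (PCVA) attributing the variance
   of the leading PCs to subject, batch, population and tissue,
5. fixed-effect batch adjustment with population as the biological
   variable (a regression analogue of supervised normalization),
6. per-gene one-way ANOVA across populations with a pooled-variance
   contrast t-statistic between the two focal populations, and
7. Benjamini–Hochberg FDR control at q <= 0.05.

The class :class:`DifferentialExpression` bundles these steps in a
statsmodels-style model whose :meth:`~DifferentialExpression.fit` returns
a :class:`DEGResults` object; the underlying steps are also exposed as
plain functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountStudy:
    """A gene x sample count matrix with per-sample annotation.

    ``annotation`` is indexed by sample and must carry at least a
    ``population`` column; ``batch``, ``subject`` and ``tissue`` are used
    where present.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.annotation.index):
            if set(self.counts.columns) != set(self.annotation.index):
                raise ValueError("count columns and annotation index disagree")
            self.annotation = self.annotation.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "population" not in self.annotation.columns:
            raise ValueError("annotation must contain a 'population' column")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


# ---------------------------------------------------------------------------
# normalization


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose 75th CPM percentile is closest
    to the mean 75th percentile. For each sample, log2 ratios (M) and mean
    log2 abundances (A) against the reference are computed over genes
    expressed in both; the stated fractions of extreme M and A values are
    trimmed; the factor is 2 to the inverse-variance-weighted mean of the
    remaining M values. Factors are scaled to geometric mean 1.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    cpm = mat / lib * 1e6
    f75 = np.percentile(cpm, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(mat.shape[1])
    yr, nr = mat[:, ref_idx], lib[ref_idx]
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        ys, ns = mat[:, j], lib[j]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no expressed genes "
                "with the TMM reference"
            )
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if np.isfinite(f):
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm_log2(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    log2((count + prior) / (effective library size in millions)), where the
    effective size is the raw total count times the sample's TMM factor.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    eff_millions = lib / 1e6
    return np.log2((counts + prior_count).divide(eff_millions, axis=1))


def abundance_filter(
    expr: pd.DataFrame,
    min_mean_log2: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes whose mean log2 abundance is below the threshold.

    Inclusive at the boundary (a gene averaging exactly the threshold is
    kept). Returns the filtered matrix plus a per-gene (mean, cv)
    diagnostic table for the coefficient-of-variation-vs-mean plot that
    motivates the threshold.
    """
    means = expr.mean(axis=1)
    sds = expr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, sds / np.abs(means), np.nan)
    diag = pd.DataFrame({"mean_log2": means, "cv": cv}, index=expr.index)
    kept = expr.loc[means >= min_mean_log2]
    return kept, diag


# ---------------------------------------------------------------------------
# variance attribution and batch adjustment


def _one_way_r2(scores: np.ndarray, labels: np.ndarray) -> float:
    """R^2 of a one-way fit of PC scores on a categorical factor."""
    grand = scores.mean()
    sst = np.sum((scores - grand) ** 2)
    if sst <= 0:
        return 0.0
    ssb = 0.0
    for lev in np.unique(labels):
        g = scores[labels == lev]
        ssb += len(g) * (g.mean() - grand) ** 2
    return float(ssb / sst)


def pcva(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    n_pcs: int = 3,
    factors: tuple[str, ...] = ("subject", "batch", "population", "tissue"),
) -> pd.DataFrame:
    """Principal-component variance analysis.

    Genes are z-standardized across samples, a sample-space PCA is taken,
    and each of the first ``n_pcs`` components' score variance is
    attributed to each annotation factor by the R^2 of a one-way fit of the
    scores on that factor. Contributions are averaged across components
    weighted by each component's variance explained; when the one-way R^2
    values of a component sum above 1 (collinear factors) they are rescaled
    to sum to 1 so the report partitions into factor shares plus residual.

    Returns a one-row-per-factor table of percent contributions with a
    final ``residual`` row; the shares sum to 100.
    """
    avail = [f for f in factors if f in annotation.columns]
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    # samples as observations
    xs = z.T
    xs = xs - xs.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    var = s[:n_pcs] ** 2
    weights = var / var.sum() if var.sum() > 0 else np.ones(n_pcs) / n_pcs
    scores = u[:, :n_pcs] * s[:n_pcs]

    contrib = {f: 0.0 for f in avail}
    residual = 0.0
    ann = annotation.loc[expr.columns]
    n_samples = len(ann)
    usable: dict[str, np.ndarray] = {}
    for f in avail:
        labels = ann[f].astype(str).to_numpy()
        n_levels = len(np.unique(labels))
        if n_levels < 2:
            warnings.warn(f"PCVA factor {f!r} is constant; contribution 0")
        elif n_levels == n_samples:
            warnings.warn(
                f"PCVA factor {f!r} has one level per sample (no replication); "
                "contribution 0"
            )
        else:
            usable[f] = labels
    for k in range(n_pcs):
        r2 = {f: (_one_way_r2(scores[:, k], usable[f]) if f in usable else 0.0)
              for f in avail}
        total = sum(r2.values())
        scale = 1.0 / total if total > 1.0 else 1.0
        for f in avail:
            contrib[f] += weights[k] * r2[f] * scale
        residual += weights[k] * max(0.0, 1.0 - total * scale)
    rows = [{"factor": f, "contribution_pct": 100.0 * contrib[f]} for f in avail]
    rows.append({"factor": "residual", "contribution_pct": 100.0 * residual})
    return pd.DataFrame(rows)


def adjust_batch(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    biological_var: str = "population",
    batch_var: str = "batch",
) -> pd.DataFrame:
    """Remove additive batch effects while preserving population effects.

    Per gene, an additive two-factor linear model (population + batch) is
    fitted by least squares and the estimated batch effects, centered so
    the grand mean is preserved, are subtracted. Exactly confounded designs
    (batch aliased with population) raise.
    """
    ann = annotation.loc[expr.columns]
    pop = pd.get_dummies(ann[biological_var].astype(str), drop_first=True, dtype=float)
    bat = pd.get_dummies(ann[batch_var].astype(str), drop_first=True, dtype=float)
    if bat.shape[1] == 0:
        return expr.copy()
    x = np.column_stack([np.ones(len(ann)), pop.to_numpy(), bat.to_numpy()])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            f"batch variable {batch_var!r} is confounded with "
            f"{biological_var!r}: batch effects are not identifiable"
        )
    y = expr.to_numpy(dtype=float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    n_pop = pop.shape[1]
    batch_cols = x[:, 1 + n_pop:]
    batch_effect = batch_cols @ coef[1 + n_pop:, :]  # samples x genes
    batch_effect -= batch_effect.mean(axis=0, keepdims=True)
    adjusted = expr.to_numpy(dtype=float) - batch_effect.T
    return pd.DataFrame(adjusted, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# per-gene testing


def per_gene_anova(expr: pd.DataFrame, groups: pd.Series, lost_df: int = 0) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per gene across populations.

    Returns a table of F statistics and exact F-distribution p-values.
    Genes with zero between-group variance get F = 0, p = 1. When the
    expression matrix was batch-adjusted beforehand, ``lost_df`` should be
    the number of batch parameters consumed (batches - 1): the adjusted
    data live in a lower-dimensional space and the residual degrees of
    freedom shrink accordingly; ignoring this makes the test
    anti-conservative.
    """
    groups = groups.loc[expr.columns].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least two populations")
    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for lev in levels:
        cols = (groups == lev).to_numpy()
        sub = x[:, cols]
        gm = sub.mean(axis=1)
        ssb += cols.sum() * (gm - grand) ** 2
        ssw += ((sub - gm[:, None]) ** 2).sum(axis=1)
    df_b = len(levels) - 1
    df_w = n - len(levels) - lost_df
    if df_w <= 0:
        raise ValueError("not enough replication for ANOVA")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    f = np.where(ssb <= 1e-300, 0.0, f)
    f = np.where((ssw <= 1e-300) & (ssb > 1e-300), np.inf, f)
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isfinite(f), f, 0.0), df_b, df_w))
    p = np.where(f == 0.0, 1.0, p)
    return pd.DataFrame({"F": f, "p_anova": p}, index=expr.index)


def contrast_tstat(
    expr: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "bloodASC",
    group_b: str = "bmLLPC",
    welch: bool = False,
) -> pd.Series:
    """Two-sample t per gene, signed as mean(group_a) - mean(group_b).

    Pooled-variance by default (so with exactly two groups, F = t^2);
    Welch's unequal-variance form via ``welch=True``.
    """
    groups = groups.loc[expr.columns].astype(str)
    a = expr.loc[:, (groups == group_a).to_numpy()].to_numpy(dtype=float)
    b = expr.loc[:, (groups == group_b).to_numpy()].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(f"need >=2 samples in both {group_a!r} and {group_b!r}")
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    if welch:
        se = np.sqrt(a.var(axis=1, ddof=1) / na + b.var(axis=1, ddof=1) / nb)
    else:
        sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
            na + nb - 2
        )
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return pd.Series(t, index=expr.index, name="t")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_degs(result: pd.DataFrame, fdr: float = 0.05) -> set[str]:
    """Genes with q <= fdr from a DEG result table."""
    if len(result) == 0 or fdr <= 0:
        return set()
    return set(result.index[result["q"] <= fdr])


# ---------------------------------------------------------------------------
# model / results


class DifferentialExpression:
    """Differential-expression model for a two-population count study.

    Parameters
    ----------
    study : CountStudy
    group_a, group_b : the focal populations for the contrast t-statistic
        (defaults are the circulating and bone-marrow plasma-cell
        populations)
    min_abundance_log2 : lower mean-abundance threshold in log2 CPM units
    adjust_batch : remove additive batch effects before testing
    prior_count : pseudo-count for the log2 CPM transform
    """

    def __init__(
        self,
        study: CountStudy,
        group_a: str = "bloodASC",
        group_b: str = "bmLLPC",
        min_abundance_log2: float = 3.0,
        adjust_batch: bool = True,
        prior_count: float = 0.5,
        welch: bool = False,
    ):
        self.study = study
        self.group_a = group_a
        self.group_b = group_b
        self.min_abundance_log2 = min_abundance_log2
        self.adjust_batch = adjust_batch
        self.prior_count = prior_count
        self.welch = welch

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, annotation: pd.DataFrame, **kw):
        return cls(CountStudy(counts, annotation), **kw)

    def fit(self, fdr: float = 0.05) -> "DEGResults":
        ann = self.study.annotation
        factors = tmm_factors(self.study.counts)
        expr = cpm_log2(self.study.counts, factors, self.prior_count)
        expr, diagnostics = abundance_filter(expr, self.min_abundance_log2)
        lost_df = 0
        if self.adjust_batch and "batch" in ann.columns and ann["batch"].nunique() > 1:
            expr = adjust_batch(expr, ann)
            lost_df = ann["batch"].nunique() - 1
        groups = ann["population"]
        anova = per_gene_anova(expr, groups, lost_df=lost_df)
        t = contrast_tstat(expr, groups, self.group_a, self.group_b, self.welch)
        q = bh_fdr(anova["p_anova"].to_numpy())
        in_a = (groups.astype(str) == self.group_a).to_numpy()
        in_b = (groups.astype(str) == self.group_b).to_numpy()
        table = pd.DataFrame(
            {
                "mean_log2": expr.mean(axis=1),
                "mean_a": expr.loc[:, in_a].mean(axis=1),
                "mean_b": expr.loc[:, in_b].mean(axis=1),
                "F": anova["F"],
                "t": t,
                "p": anova["p_anova"],
                "q": q,
            },
            index=expr.index,
        )
        table["is_deg"] = table["q"] <= fdr
        return DEGResults(
            model=self, table=table, expr=expr, factors=factors,
            diagnostics=diagnostics, fdr=fdr,
        )


@dataclass
class DEGResults:
    """Fitted differential-expression results.

    ``table`` has one row per tested gene with mean abundances, the ANOVA
    F, the contrast t (group_a minus group_b), p, BH q, and the DEG flag.
    """

    model: DifferentialExpression
    table: pd.DataFrame
    expr: pd.DataFrame
    factors: pd.Series
    diagnostics: pd.DataFrame
    fdr: float = 0.05
    _pcva_cache: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def deg_genes(self) -> set[str]:
        return call_degs(self.table, self.fdr)

    @property
    def ranking(self) -> pd.Series:
        """Contrast t-statistic ranking for pre-ranked enrichment."""
        return self.table["t"].copy()

    def pcva(self, n_pcs: int = 3) -> pd.DataFrame:
        if self._pcva_cache is None:
            self._pcva_cache = pcva(self.expr, self.model.study.annotation, n_pcs)
        return self._pcva_cache

    def summary(self) -> str:
        n = len(self.table)
        n_deg = int(self.table["is_deg"].sum())
        up = int(((self.table["t"] > 0) & self.table["is_deg"]).sum())
        lines = [
            "Differential expression summary",
            "===============================",
            f"populations contrasted : {self.model.group_a} vs {self.model.group_b}",
            f"samples                : {self.model.study.counts.shape[1]}",
            f"genes tested           : {n} (abundance >= "
            f"{self.model.min_abundance_log2} log2 CPM)",
            f"batch adjustment       : {'on' if self.model.adjust_batch else 'off'}",
            f"DEG at q <= {self.fdr:g}      : {n_deg} "
            f"({up} higher in {self.model.group_a}, {n_deg - up} higher in "
            f"{self.model.group_b})",
        ]
        return "\n".join(lines)
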