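"""Pre-ranked gene-set enrichment and gene-set summarization.

Genes are ranked by the contrast t-statistic (blood ASC minus BM LLPC) and
each gene set's enrichment score (ES) is the signed maximum deviation of a
weighted Kolmogorov–Smirnov-like running sum: set members ("hits")
increment the sum by |score|^p normalized over the set, non-members
("misses") decrement it by 1/(N - |S|). Significance comes from gene-label
permutation: null ES distributions per set, sign-matched normalization to
NES, and the pooled-NES FDR procedure. "High or low expression" is read as
two-sided — both ES signs are tested and the direction is reported.

Set-level summarization follows the source study's pattern: per-gene
standardized least-square means across populations, per-set PC1
(eigengene) scores, and Ward hierarchical clustering of the set profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._rng import stream


class GeneSetCollection:
    """Named gene sets (GMT-style)."""

    def __init__(self, sets: dict[str, set[str]], descriptions: dict[str, str] | None = None):
        self.sets = {name: set(members) for name, members in sets.items()}
        self.descriptions = descriptions or {}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        desc: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}: malformed GMT row at line {lineno}")
                name, description, members = parts[0], parts[1], parts[2:]
                sets[name] = {m.upper() for m in members if m}
                desc[name] = description
        return cls(sets, desc)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{self.descriptions.get(name, '')}\t{members}\n")


# ---------------------------------------------------------------------------
# enrichment score


def _prepare_ranking(ranking: pd.Series) -> pd.Series:
    """Sort scores descending, breaking ties by gene symbol."""
    df = pd.DataFrame(
        {"score": ranking.to_numpy(dtype=float), "gene": ranking.index.astype(str)}
    )
    df = df.sort_values(["score", "gene"], ascending=[False, True])
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy())


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_genes: int
) -> np.ndarray:
    """Enrichment scores for one or many hit-position sets.

    ``positions``: (n_draws, set_size) sorted 0-based positions in the
    ranked list; ``weights``: |score|^p of every ranked gene. The running
    sum changes only at hits, so the extremum is attained either just after
    a hit or just before one; both candidate sets are evaluated.
    """
    n_draws, s = positions.shape
    miss = 1.0 / (n_genes - s)
    w = weights[positions]  # (n_draws, s)
    wsum = w.sum(axis=1, keepdims=True)
    # degenerate all-zero weights (e.g. every score 0 with p>0): fall back
    # to the unweighted form
    w = np.where(wsum > 0, w, 1.0)
    wsum = np.where(wsum > 0, wsum, float(s))
    cum_hit = np.cumsum(w, axis=1) / wsum
    k = np.arange(1, s + 1)
    after = cum_hit - (positions + 1 - k) * miss
    before = np.concatenate(
        [np.zeros((n_draws, 1)), cum_hit[:, :-1]], axis=1
    ) - (positions - (k - 1)) * miss
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    # signed extremum. Exact ties between the positive and negative
    # excursion are structurally common (e.g. every miss outside the hit
    # run), so the positive side wins unless the negative deviation is
    # larger by more than a 1e-9 relative margin — the documented
    # convention of this statistic.
    tol = 1e-9 * np.maximum(1.0, np.maximum(hi, -lo))
    return np.where(hi >= -lo - tol, hi, lo)


def enrichment_score(
    ranking: pd.Series, gene_set: set[str], weight_exponent: float = 1.0
) -> float:
    """ES of a single gene set against a ranked list (sorted internally)."""
    ranked = _prepare_ranking(ranking)
    members = np.isin(ranked.index.to_numpy(), list(gene_set))
    if members.sum() == 0 or members.all():
        raise ValueError("gene set must hit a strict subset of the ranked universe")
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    pos = np.flatnonzero(members)[None, :]
    return float(_es_from_positions(pos, weights, len(ranked))[0])


@dataclass
class GseaResults:
    """Per-set enrichment statistics plus leading-edge genes.

    ``table`` columns: set, size, ES, NES, p, q, direction (high = enriched
    toward the top of the ranking, i.e. the group_a side of the contrast).
    """

    table: pd.DataFrame
    leading_edge: dict[str, list[str]]
    n_perm: int
    seed: int | None

    def significant(self, fdr: float = 0.05) -> list[str]:
        t = self.table
        return t.loc[t["q"] <= fdr, "set"].tolist()

    def summary(self, fdr: float = 0.05) -> str:
        sig = self.significant(fdr)
        lines = [
            "Pre-ranked GSEA summary",
            "=======================",
            f"gene sets tested   : {len(self.table)}",
            f"permutations       : {self.n_perm}",
            f"significant (q<={fdr:g}) : {len(sig)}",
        ]
        for name in sig[:20]:
            row = self.table.set_index("set").loc[name]
            lines.append(
                f"  {name}: NES={row['NES']:+.2f} q={row['q']:.3g} ({row['direction']})"
            )
        return "\n".join(lines)


class PrerankedGSEA:
    """Pre-ranked GSEA model over a score ranking and a gene-set collection."""

    def __init__(
        self,
        ranking: pd.Series,
        sets: GeneSetCollection,
        weight_exponent: float = 1.0,
        min_size: int = 5,
        max_size: int = 500,
    ):
        self.ranking = ranking
        self.sets = sets
        self.weight_exponent = weight_exponent
        self.min_size = min_size
        self.max_size = max_size

    def fit(self, n_perm: int = 1000, seed: int | None = None) -> GseaResults:
        return gsea_preranked(
            self.ranking, self.sets, self.weight_exponent, n_perm,
            self.min_size, self.max_size, seed,
        )


def gsea_preranked(
    ranking: pd.Series,
    sets: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int | None = None,
) -> GseaResults:
    """Pre-ranked GSEA with gene-label permutation FDR.

    Null distributions are drawn by resampling random same-size gene sets
    from the ranked universe (with pre-ranked input, phenotype permutation
    is impossible). NES = ES divided by the mean magnitude of same-sign
    null ES; q-values follow the pooled-NES procedure with a final running
    minimum toward less extreme NES.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; FDR estimates will be unstable")
    ranked = _prepare_ranking(ranking)
    genes = ranked.index.to_numpy()
    n = len(genes)
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    rng = stream(0 if seed is None else seed, "gsea")

    rows = []
    leading: dict[str, list[str]] = {}
    null_nes_all: list[np.ndarray] = []
    gene_pos = {g: i for i, g in enumerate(genes)}

    for name in sorted(sets.sets):
        members = sorted(sets.sets[name] & set(genes))
        s = len(members)
        if s == 0:
            warnings.warn(f"gene set {name!r} shares no genes with the ranking; skipped")
            continue
        if s < min_size or s > max_size or s == n:
            continue
        pos = np.sort(np.array([gene_pos[g] for g in members]))
        es = float(_es_from_positions(pos[None, :], weights, n)[0])

        # null: random same-size subsets of the universe
        r = rng.random((n_perm, n))
        null_pos = np.sort(np.argpartition(r, s - 1, axis=1)[:, :s], axis=1)
        null_es = _es_from_positions(null_pos, weights, n)

        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        if es >= 0:
            denom = pos_null.mean() if len(pos_null) else np.nan
            same = pos_null
        else:
            denom = np.abs(neg_null).mean() if len(neg_null) else np.nan
            same = neg_null
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        n_same = len(same)
        n_extreme = int(np.sum(np.abs(same) >= abs(es))) if n_same else 0
        p = (1 + n_extreme) / (1 + n_same) if n_same else 1.0

        # normalize the null ES of this set to null NES
        null_nes = np.full(n_perm, np.nan)
        if len(pos_null):
            m_pos = pos_null.mean()
            if m_pos > 0:
                null_nes[null_es >= 0] = null_es[null_es >= 0] / m_pos
        if len(neg_null):
            m_neg = np.abs(neg_null).mean()
            if m_neg > 0:
                null_nes[null_es < 0] = null_es[null_es < 0] / m_neg
        null_nes_all.append(null_nes[np.isfinite(null_nes)])

        # leading edge: members at or before the running-sum extremum
        es_row = _running_extremum_position(pos, weights, n, es)
        leading[name] = [genes[i] for i in pos if (i <= es_row if es >= 0 else i >= es_row)]
        rows.append(
            {"set": name, "size": s, "ES": es, "NES": nes, "p": p,
             "direction": "high" if es >= 0 else "low"}
        )

    table = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "p", "direction"])
    if len(table):
        pooled = np.concatenate(null_nes_all) if null_nes_all else np.array([])
        table["q"] = _pooled_nes_fdr(table["NES"].to_numpy(), pooled)
    else:
        table["q"] = pd.Series(dtype=float)
    table = table[["set", "size", "ES", "NES", "p", "q", "direction"]]
    table = table.sort_values("q", kind="stable").reset_index(drop=True)
    return GseaResults(table=table, leading_edge=leading, n_perm=n_perm, seed=seed)


def _running_extremum_position(pos, weights, n_genes, es) -> int:
    """Ranked-list position at which the running sum attains the ES."""
    s = len(pos)
    miss = 1.0 / (n_genes - s)
    w = weights[pos]
    wsum = w.sum()
    if wsum <= 0:
        w = np.ones(s)
        wsum = float(s)
    cum_hit = np.cumsum(w) / wsum
    k = np.arange(1, s + 1)
    after = cum_hit - (pos + 1 - k) * miss
    before = np.concatenate([[0.0], cum_hit[:-1]]) - (pos - (k - 1)) * miss
    if es >= 0:
        return int(pos[int(np.argmax(after))])
    return int(pos[int(np.argmin(before))])


def _pooled_nes_fdr(obs_nes: np.ndarray, pooled_null: np.ndarray) -> np.ndarray:
    """Standard pooled-NES FDR: tail fraction of the pooled null beyond each
    observed NES over the matching tail fraction of the observed NES, with a
    running minimum toward less extreme values within each sign."""
    q = np.ones(len(obs_nes))
    finite = np.isfinite(obs_nes)
    if not finite.any() or len(pooled_null) == 0:
        return q
    null_pos = pooled_null[pooled_null >= 0]
    null_neg = pooled_null[pooled_null < 0]
    obs = obs_nes[finite]
    n_obs_pos = int(np.sum(obs >= 0))
    n_obs_neg = int(np.sum(obs < 0))
    for i, nes in zip(np.flatnonzero(finite), obs):
        if nes >= 0:
            if len(null_pos) == 0 or n_obs_pos == 0:
                q[i] = 0.0 if len(null_pos) == 0 else 1.0
                continue
            num = np.mean(null_pos >= nes)
            den = np.sum(obs >= nes) / n_obs_pos
        else:
            if len(null_neg) == 0 or n_obs_neg == 0:
                q[i] = 0.0 if len(null_neg) == 0 else 1.0
                continue
            num = np.mean(null_neg <= nes)
            den = np.sum(obs[obs < 0] <= nes) / n_obs_neg
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    # step-up monotonicity within each sign: a more extreme NES takes the
    # minimum raw ratio over all less-extreme sets (as in BH), so q never
    # increases with |NES|
    for sign in (1, -1):
        idx = np.flatnonzero(finite & ((obs_nes >= 0) if sign == 1 else (obs_nes < 0)))
        if len(idx) == 0:
            continue
        order = idx[np.argsort(np.abs(obs_nes[idx]), kind="stable")]  # least extreme first
        best = np.inf
        for i in order:
            best = min(best, q[i])
            q[i] = best
    return q


# ---------------------------------------------------------------------------
# gene-set summarization


def standardize_slsm(
    expr: pd.DataFrame, groups: pd.Series, adjust: pd.Series | None = None
) -> pd.DataFrame:
    """Standardized least-square means: per-gene group means, z-scored
    across groups (sample-SD convention, ddof=1).

    With ``adjust`` (e.g. batch), group means come from an additive
    two-factor model averaged over the adjustment levels; otherwise they
    are plain group means. Genes constant across groups map to all-zero
    rows with a warning.
    """
    groups = groups.loc[expr.columns].astype(str)
    levels = sorted(groups.unique())
    if adjust is not None:
        from .degs import adjust_batch

        ann = pd.DataFrame({"population": groups, "batch": adjust.loc[expr.columns]})
        expr = adjust_batch(expr, ann)
    means = pd.DataFrame(
        {lev: expr.loc[:, (groups == lev).to_numpy()].mean(axis=1) for lev in levels}
    )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    flat = sd <= 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} genes constant across groups; set to 0")
    sd = sd.where(~flat, 1.0)
    out = means.sub(mu, axis=0).div(sd, axis=0)
    out[flat] = 0.0
    return out


def geneset_pc1(slsm: pd.DataFrame, gene_set: set[str]) -> tuple[pd.Series, float]:
    """Eigengene of a gene set: PC1 scores per group/sample column plus the
    fraction of variance explained.

    The sign is oriented to correlate positively with the set's mean
    profile (falling back to a positive first component)."""
    members = sorted(set(gene_set) & set(slsm.index))
    if not members:
        raise ValueError("gene set shares no genes with the SLSM matrix")
    m = slsm.loc[members].to_numpy(dtype=float)
    if m.shape[0] == 1:
        return pd.Series(m[0], index=slsm.columns, name="PC1"), 1.0
    u, s, vt = np.linalg.svd(m - m.mean(axis=1, keepdims=True), full_matrices=False)
    scores = s[0] * vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2)) if np.sum(s**2) > 0 else 1.0
    mean_profile = m.mean(axis=0)
    orient = np.dot(scores, mean_profile - mean_profile.mean())
    if orient < 0 or (orient == 0 and _first_nonzero_sign(scores) < 0):
        scores = -scores
    return pd.Series(scores, index=slsm.columns, name="PC1"), var_explained


def _first_nonzero_sign(x: np.ndarray) -> float:
    nz = x[x != 0]
    return float(np.sign(nz[0])) if len(nz) else 1.0


def ward_cluster(profiles: pd.DataFrame) -> np.ndarray:
    """Ward-criterion agglomerative clustering (Euclidean distance) of the
    rows of ``profiles``; returns a scipy linkage matrix."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    return hierarchy.linkage(profiles.to_numpy(dtype=float), method="ward")


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"


def hypergeometric_overlap(
    query: set[str], target: set[str], universe: set[str]
) -> tuple[float, float]:
    """Upper-tail hypergeometric p-value and fold enrichment of the overlap
    between two gene sets within a universe."""
    universe = set(universe)
    q = set(query) & universe
    t = set(target) & universe
    k = len(q & t)
    m, nq, nt = len(universe), len(q), len(t)
    if nq == 0 or nt == 0:
        raise ValueError("query and target must intersect the universe")
    p = float(stats.hypergeom.sf(k - 1, m, nt, nq))
    expected = nq * nt / m
    fold = k / expected if expected > 0 else np.inf
    return p, fold


@dataclass
class EigengeneSummary:
    """Per-set PC1 profiles with Ward linkage over sets."""

    pc1: pd.DataFrame  # sets x groups
    variance_explained: pd.Series
    linkage: np.ndarray | None
    newick: str | None

    def to_dict(self) -> dict:
        return {
            "pc1": {s: self.pc1.loc[s].round(6).to_dict() for s in self.pc1.index},
            "variance_explained": self.variance_explained.round(6).to_dict(),
            "newick": self.newick,
        }


def summarize_gene_sets(
    expr: pd.DataFrame,
    groups: pd.Series,
    sets: GeneSetCollection,
    set_names: list[str] | None = None,
) -> EigengeneSummary:
    """SLSM → per-set PC1 → Ward clustering, for the named sets (default all
    sets that intersect the expression matrix)."""
    slsm = standardize_slsm(expr, groups)
    names = set_names if set_names is not None else sorted(sets.sets)
    pc1_rows, varex = {}, {}
    for name in names:
        members = sets.sets[name] & set(slsm.index)
        if not members:
            continue
        scores, ve = geneset_pc1(slsm, members)
        pc1_rows[name] = scores
        varex[name] = ve
    if not pc1_rows:
        raise ValueError("no gene set overlaps the expression matrix")
    pc1 = pd.DataFrame(pc1_rows).T
    if len(pc1) >= 2:
        link = ward_cluster(pc1)
        newick = linkage_to_newick(link, list(pc1.index))
    else:
        link, newick = None, None
    return EigengeneSummary(
        pc1=pc1, variance_explained=pd.Series(varex), linkage=link, newick=newick
    )
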