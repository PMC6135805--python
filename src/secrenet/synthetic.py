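"""Synthetic study generator with planted ground truth.

Every input the prioritization pipeline consumes can be generated here at
desk scale with a known answer: a sparse weighted PPI graph whose hubs act
as planted "secretome factors", a negative-binomial count study in which
the factors' network neighbors are preferentially differentially
expressed, multi-fraction protein identification lists sharing a common
background, target/decoy PSM score mixtures, gene-set collections with a
known enriched subset, and Poisson Elispot decay series.

Conventions
-----------
* Gene symbols are synthetic tokens ``G000001``…; planted factor nodes are
  relabeled ``F01``… for readability.
* Counts are negative binomial in the mean–dispersion form, variance
  mu + phi * mu^2, with a single dispersion phi per run.
* Batch effects are additive on the log2 scale: each batch carries one
  gene-wise N(0, batch_effect_sd) offset vector shared by all its samples,
  which makes the batch share of PCVA variance tunable through
  ``batch_effect_sd`` alone (a scalar per-batch shift would be equivalent
  to a library-size change and vanish under CPM normalization).
* Library sizes are drawn log-uniform within ``lib_size_range`` so TMM has
  real work to do.
* All randomness flows from one integer seed through named substreams
  (see :mod:`secrenet._rng`), so each generator reproduces exactly what a
  full pipeline run with the same master seed produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import stream
from .degs import CountStudy
from .enrichment import GeneSetCollection
from .network import PPINetwork
from .proteomics import FractionProteome
from .survival import ElispotSeries


@dataclass
class SyntheticTruth:
    """Everything that was planted, for downstream verification."""

    planted_factors: list[str] = field(default_factory=list)
    planted_deg: dict[str, float] = field(default_factory=dict)  # gene -> signed lfc
    enriched_sets: list[str] = field(default_factory=list)
    batch_assignment: dict[str, str] = field(default_factory=dict)
    batch_effect_sd: float = 0.0
    neighbor_de_prob: float = 0.0
    background_de_prob: float = 0.0

    def to_dict(self) -> dict:
        return {
            "planted_factors": list(self.planted_factors),
            "planted_deg": {g: float(v) for g, v in sorted(self.planted_deg.items())},
            "enriched_sets": list(self.enriched_sets),
            "batch_assignment": dict(self.batch_assignment),
            "batch_effect_sd": self.batch_effect_sd,
            "neighbor_de_prob": self.neighbor_de_prob,
            "background_de_prob": self.background_de_prob,
        }


# ---------------------------------------------------------------------------
# network


def generate_ppi_network(
    n_nodes: int = 500,
    n_edges: int = 2000,
    attachment_bias: float = 1.0,
    seed: int = 0,
) -> PPINetwork:
    """Random simple graph with a right-skewed degree distribution.

    A random spanning tree is grown first (attachment probability
    proportional to (degree + 1)^bias, so bias > 0 yields preferential
    attachment and hubs), then the remaining edges are added between
    degree-biased endpoint pairs, rejecting self-loops and duplicates.
    Edge confidences are uniform(0.5, 1.0).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_edges < n_nodes - 1:
        raise ValueError(f"n_edges={n_edges} cannot connect {n_nodes} nodes")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"n_edges={n_edges} exceeds the simple-graph maximum {max_edges}"
        )
    rng = stream(seed, "network")
    names = [f"G{i + 1:06d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    deg = np.zeros(n_nodes)

    def pick(exclude: int | None = None) -> int:
        w = (deg + 1.0) ** attachment_bias
        if exclude is not None:
            w = w.copy()
            w[exclude] = 0.0
        return int(rng.choice(n_nodes, p=w / w.sum()))

    # spanning tree over a random node order
    order = rng.permutation(n_nodes)
    attached = [order[0]]
    mask = np.zeros(n_nodes, dtype=bool)
    mask[order[0]] = True
    for i in order[1:]:
        w = (deg + 1.0) ** attachment_bias * mask
        j = int(rng.choice(n_nodes, p=w / w.sum()))
        g.add_edge(names[i], names[j])
        deg[i] += 1
        deg[j] += 1
        mask[i] = True
        attached.append(i)
    while g.number_of_edges() < n_edges:
        a = pick()
        b = pick(exclude=a)
        if g.has_edge(names[a], names[b]):
            continue
        g.add_edge(names[a], names[b])
        deg[a] += 1
        deg[b] += 1
    net = PPINetwork()
    for a, b in sorted(g.edges()):
        net.add_edge(a, b, confidence=float(rng.uniform(0.5, 1.0)))
    return net


def plant_factors(
    network: PPINetwork,
    n_factors: int = 5,
    min_degree: int = 15,
    seed: int = 0,
    relabel: bool = True,
) -> list[str]:
    """Choose hub nodes to act as planted secretome survival factors.

    Picks ``n_factors`` distinct nodes of degree >= ``min_degree``
    uniformly at random. With ``relabel`` (default) the chosen nodes are
    renamed ``F01``… in the network for readability, and the new names are
    returned.
    """
    rng = stream(seed, "factors")
    eligible = sorted(n for n in network.nodes if network.degree(n) >= min_degree)
    if len(eligible) < n_factors:
        degs = sorted((network.degree(n) for n in network.nodes), reverse=True)
        achievable = degs[n_factors - 1] if len(degs) >= n_factors else 0
        raise ValueError(
            f"only {len(eligible)} nodes have degree >= {min_degree}; "
            f"the largest feasible min_degree for {n_factors} factors is {achievable}"
        )
    chosen = sorted(rng.choice(eligible, size=n_factors, replace=False).tolist())
    if not relabel:
        return chosen
    mapping = {old: f"F{i + 1:02d}" for i, old in enumerate(chosen)}
    network.graph = nx.relabel_nodes(network.graph, mapping, copy=True)
    return [mapping[old] for old in chosen]


# ---------------------------------------------------------------------------
# counts


def generate_counts(
    network: PPINetwork | None = None,
    factors: list[str] | None = None,
    n_genes: int = 2000,
    samples_per_group: tuple[int, int] = (8, 4),
    neighbor_de_prob: float = 0.5,
    background_de_prob: float = 0.05,
    lfc_scale: float = 1.5,
    dispersion: float = 0.1,
    lib_size_range: tuple[int, int] = (500_000, 2_000_000),
    batch_effect_sd: float = 1.0,
    n_batches: int = 2,
    seed: int = 0,
    group_labels: tuple[str, str] = ("bloodASC", "bmLLPC"),
) -> tuple[CountStudy, SyntheticTruth]:
    """Negative-binomial count study with planted differential expression.

    The gene universe is the network's nodes padded with extra ``G``
    tokens up to ``n_genes``. Neighbors of the planted factors are
    differentially expressed between the two populations with probability
    ``neighbor_de_prob``; all other genes with ``background_de_prob``.
    Planted genes get a log2 fold-change of magnitude ``lfc_scale`` with a
    random sign, applied to the second population. Batches are assigned
    round-robin within each population (so batch is never confounded with
    population) and shift all genes of their samples by a common
    N(0, batch_effect_sd) log2 offset.
    """
    if samples_per_group[0] < 1 or samples_per_group[1] < 1:
        raise ValueError("samples_per_group entries must be positive")
    if not (0 <= neighbor_de_prob <= 1 and 0 <= background_de_prob <= 1):
        raise ValueError("DE probabilities must lie in [0, 1]")
    rng = stream(seed, "counts")

    nodes = sorted(network.nodes) if network is not None else []
    factors = list(factors or [])
    if n_genes < len(nodes):
        raise ValueError("n_genes must cover all network nodes")
    extra = [f"G{i + 1:06d}" for i in range(10**5, 10**5 + n_genes - len(nodes))]
    genes = nodes + extra

    neighbor_set: set[str] = set()
    if network is not None:
        for f in factors:
            if f not in network.nodes:
                raise ValueError(f"factor {f!r} is not a network node")
            neighbor_set |= network.neighbors(f)
    neighbor_set -= set(factors)

    # planted DE assignment
    lfc = {}
    for g in genes:
        p = neighbor_de_prob if g in neighbor_set else background_de_prob
        if rng.random() < p:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc[g] = sign * lfc_scale

    na, nb = samples_per_group
    samples = [f"A{i + 1:02d}" for i in range(na)] + [f"B{i + 1:02d}" for i in range(nb)]
    population = [group_labels[0]] * na + [group_labels[1]] * nb
    tissue = ["blood"] * na + ["bone_marrow"] * nb
    subject = [f"S{i + 1:02d}" for i in range(na + nb)]
    batch = [f"batch{(i % n_batches) + 1}" for i in range(na)] + [
        f"batch{(i % n_batches) + 1}" for i in range(nb)
    ]

    # gene baselines: relative log2 abundance uniform in (-3, 9); after
    # per-sample normalization to library proportions the realized log2 CPM
    # is shifted by a common constant (~+3 at the 2000-gene default), so
    # roughly the bottom quarter of genes falls below the 3-log2 filter
    base_log2_cpm = rng.uniform(-3.0, 9.0, size=len(genes))
    lib_sizes = np.exp(
        rng.uniform(np.log(lib_size_range[0]), np.log(lib_size_range[1]), size=len(samples))
    )
    # one gene-wise log2 offset vector per batch, shared by the batch's
    # samples; a scalar shift per batch would be indistinguishable from
    # library size and vanish under CPM normalization
    batch_shift = {
        f"batch{b + 1}": (
            rng.normal(0.0, batch_effect_sd, size=len(genes))
            if batch_effect_sd > 0
            else np.zeros(len(genes))
        )
        for b in range(n_batches)
    }

    lfc_vec = np.array([lfc.get(g, 0.0) for g in genes])
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        log2_cpm = base_log2_cpm + batch_shift[batch[j]]
        if j >= na:  # second population carries the fold-change
            log2_cpm = log2_cpm + lfc_vec
        rate = 2.0 ** log2_cpm
        mu = rate / rate.sum() * lib_sizes[j]
        if dispersion <= 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    annotation = pd.DataFrame(
        {"population": population, "batch": batch, "subject": subject, "tissue": tissue},
        index=samples,
    )
    truth = SyntheticTruth(
        planted_factors=factors,
        planted_deg=lfc,
        batch_assignment=dict(zip(samples, batch)),
        batch_effect_sd=batch_effect_sd,
        neighbor_de_prob=neighbor_de_prob,
        background_de_prob=background_de_prob,
    )
    return CountStudy(counts_df, annotation), truth


# ---------------------------------------------------------------------------
# fraction proteomes


def generate_fraction_proteomes(
    factors: list[str],
    background_size: int = 100,
    active_labels: tuple[str, ...] = (
        "iMSC_secretome",
        "noniMSC_secretome",
        "iMSC_supernatant",
    ),
    inactive_labels: tuple[str, ...] = ("noniMSC_supernatant", "SBAC"),
    dropout_rate: float = 0.0,
    contaminant_rate: float = 0.05,
    seed: int = 0,
) -> list[FractionProteome]:
    """Protein identification lists per secretome fraction.

    Active (bioactive) fractions contain each planted factor with
    probability 1 - dropout_rate plus a shared serum background; inactive
    fractions contain the background plus random contaminants but never
    factors; one extra fraction labeled ``FBS_background`` holds the
    background alone.
    """
    if set(active_labels) & set(inactive_labels):
        raise ValueError("active and inactive labels must be disjoint")
    if not (0 <= dropout_rate <= 1 and 0 <= contaminant_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = stream(seed, "fractions")
    background = {f"BG{i + 1:04d}" for i in range(background_size)}
    contaminant_pool = [f"CT{i + 1:04d}" for i in range(max(background_size, 50))]

    fractions: list[FractionProteome] = []
    for label in active_labels:
        detected = {f for f in factors if rng.random() >= dropout_rate}
        fractions.append(
            FractionProteome(label, "bioactive", detected | set(background))
        )
    for label in inactive_labels:
        n_cont = rng.binomial(len(contaminant_pool), contaminant_rate)
        cont = set(rng.choice(contaminant_pool, size=n_cont, replace=False).tolist())
        fractions.append(FractionProteome(label, "inactive", cont | set(background)))
    fractions.append(FractionProteome("FBS_background", "background", set(background)))
    return fractions


# ---------------------------------------------------------------------------
# PSM tables


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_psm_table(
    n_true: int = 500,
    n_null_targets: int = 1000,
    n_decoys: int = 1000,
    true_score_mean: float = 3.0,
    null_score_mean: float = 0.0,
    score_sd: float = 1.0,
    seed: int = 0,
    protein_pool: list[str] | None = None,
) -> pd.DataFrame:
    """Target/decoy PSM score mixture with hidden truth labels.

    Decoy and null-target scores share one normal distribution; true
    targets are shifted upward. The defaults keep n_null_targets equal to
    n_decoys, matching the concatenated-search premise that an incorrect
    identification lands on the target and decoy database with equal
    probability. Peptide lengths are uniform in 6..30 so the >=7-residue
    filter is exercised. The hidden ``is_true`` column records which
    targets are genuine.
    """
    rng = stream(seed, "psm")
    n = n_true + n_null_targets + n_decoys
    lengths = rng.integers(6, 31, size=n)
    peptides = ["".join(rng.choice(_AA, size=int(L))) for L in lengths]
    scores = np.concatenate(
        [
            rng.normal(true_score_mean, score_sd, size=n_true),
            rng.normal(null_score_mean, score_sd, size=n_null_targets),
            rng.normal(null_score_mean, score_sd, size=n_decoys),
        ]
    )
    is_decoy = np.array([False] * (n_true + n_null_targets) + [True] * n_decoys)
    is_true = np.array([True] * n_true + [False] * (n_null_targets + n_decoys))
    if protein_pool:
        true_proteins = rng.choice(protein_pool, size=n_true).tolist()
    else:
        true_proteins = [f"TP{i + 1:05d}" for i in range(n_true)]
    proteins = (
        true_proteins
        + [f"NT{i + 1:05d}" for i in range(n_null_targets)]
        + [f"DECOY_{i + 1:05d}" for i in range(n_decoys)]
    )
    df = pd.DataFrame(
        {
            "peptide": peptides,
            "protein": proteins,
            "length": lengths,
            "score": scores,
            "is_decoy": is_decoy,
            "is_true": is_true,
        }
    )
    return df.sample(frac=1.0, random_state=int(stream(seed, "psm").integers(2**31))).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    universe: list[str],
    n_sets: int = 30,
    size_range: tuple[int, int] = (20, 80),
    n_enriched: int = 5,
    truth: SyntheticTruth | None = None,
    enrichment_factor: float = 5.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene-set collection with a planted enriched subset.

    The first ``n_enriched`` sets draw each member slot from the planted
    DE genes with probability min(1, enrichment_factor * base_rate) where
    base_rate is the DE fraction of the universe (so the expected DE
    content is enrichment_factor times the background, capped by
    availability); the remaining sets sample uniformly. Each enriched set
    prefers DE genes of one randomly chosen fold-change direction,
    mirroring the directional coherence of real dysregulated pathways (a
    pathway's members move together between tissues); without it the two
    signs cancel in a running-sum enrichment statistic. Enriched set names
    are recorded in ``truth.enriched_sets``.
    """
    rng = stream(seed, "gene_sets")
    universe = list(universe)
    de_genes = sorted(set(truth.planted_deg) & set(universe)) if truth else []
    non_de = sorted(set(universe) - set(de_genes))
    base_rate = len(de_genes) / len(universe) if universe else 0.0
    p_de = min(1.0, enrichment_factor * base_rate) if de_genes else 0.0

    sets: dict[str, set[str]] = {}
    enriched_names = []
    for i in range(n_sets):
        name = f"SET_{i + 1:03d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(universe))
        if i < n_enriched and de_genes:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            pool = [g for g in de_genes
                    if truth.planted_deg[g] * direction > 0] or de_genes
            n_from_de = min(int(rng.binomial(size, p_de)), len(pool), size)
            picked = set(rng.choice(pool, size=n_from_de, replace=False).tolist())
            rest = size - len(picked)
            if rest > 0:
                pool = non_de if len(non_de) >= rest else sorted(set(universe) - picked)
                picked |= set(rng.choice(pool, size=rest, replace=False).tolist())
            enriched_names.append(name)
        else:
            picked = set(rng.choice(universe, size=size, replace=False).tolist())
        sets[name] = picked
    if truth is not None:
        truth.enriched_sets = enriched_names
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Elispot series


DEFAULT_ELISPOT_CONDITIONS = (
    ("secretome", 1.0, 0.08),
    ("media", 1.0, 1.2),
)


def generate_elispot_series(
    conditions=DEFAULT_ELISPOT_CONDITIONS,
    days: tuple[int, ...] = (1, 2, 3, 7, 14),
    wells_per_day: int = 3,
    max_spots: int = 100,
    seed: int = 0,
) -> list[ElispotSeries]:
    """Poisson Elispot decay curves.

    Per-well counts are Poisson(max_spots * day0_frac * exp(-decay * day))
    for each (name, day0_frac, decay_rate_per_day) condition.
    """
    rng = stream(seed, "elispot")
    out = []
    for name, day0_frac, decay in conditions:
        rows = []
        for day in days:
            lam = max_spots * day0_frac * np.exp(-decay * day)
            for well in range(wells_per_day):
                rows.append({"day": int(day), "well": well, "spots": int(rng.poisson(lam))})
        out.append(ElispotSeries(name, pd.DataFrame(rows)))
    return out
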