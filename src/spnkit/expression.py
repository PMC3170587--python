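"""Downstream expression analytics.

Per-sample z-normalization, Pearson-distance hierarchical clustering with
heatmaps, clustering-coherence comparison against size-matched random gene
sets, and a global-test statistic for association of a gene group's
expression with a binary outcome:

    Q = e' (X X' / m) e / (mu (1 - mu)),   e = y - mu,  mu = mean(y)

where X is the n x m sample-by-gene matrix with genes centered across
samples.  Q aggregates, over genes, the squared covariance between each
gene's expression and the outcome residual; its null distribution and the
p-value come from permuting the outcome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .datamodel import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    gene_linkage: np.ndarray | None
    sample_linkage: np.ndarray
    gene_leaves: list[str]
    sample_leaves: list[str]
    linkage_method: str
    coherence: float  # adjusted Rand index of the labeled-k cut vs true labels


@dataclass(frozen=True)
class GeneGroup:
    name: str
    gene_ids: tuple[str, ...]
    provenance: str = "marker_window"

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"group {self.name}: duplicate gene ids")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))


@dataclass(frozen=True)
class GlobalTestResult:
    """One row of the gene-group association report: group size, how many of
    its genes the matrix covers, the observed statistic Q, its permutation
    mean and sd, and the permutation p-value."""

    group: str
    n_genes: int
    n_tested: int
    Q: float
    expected_Q: float
    sd_Q: float
    p_value: float


def znormalize_samples(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Transform each sample (column) to mean 0, population sd 1.

    Idempotent up to numerical tolerance; a constant sample is an error since
    its profile carries no contrast to standardize.
    """
    v = expr.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=0)
    constant = sd[sd == 0.0]
    if len(constant):
        raise ValueError(f"constant expression in sample(s) {list(constant.index)}")
    return ExpressionMatrix((v - mean) / sd, expr.sample_labels)


def pearson_distance_matrix(data: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson r distances between the rows of ``data``."""
    return pdist(data.to_numpy(), metric="correlation")


def hierarchical_cluster(
    expr: ExpressionMatrix,
    group: GeneGroup,
    labels: Mapping[str, str] | None = None,
    method: str = "average",
    cluster_genes: bool = True,
) -> ClusteringResult:
    """Average-linkage agglomeration on 1 - Pearson r, both axes.

    Coherence is the adjusted Rand index between the sample dendrogram cut at
    k = number of distinct labels and the labels themselves.
    """
    sub = expr.subset_genes(group.gene_ids)
    if sub.shape[0] < 2:
        raise ValueError(
            f"group {group.name}: only {sub.shape[0]} of its genes present in the matrix"
        )
    labels = dict(labels) if labels is not None else dict(expr.sample_labels)

    gene_linkage = None
    gene_leaves = sub.gene_ids
    if cluster_genes:
        gene_linkage = hierarchy.linkage(pearson_distance_matrix(sub.values), method=method)
        gene_leaves = [sub.gene_ids[i] for i in hierarchy.leaves_list(gene_linkage)]
    sample_linkage = hierarchy.linkage(pearson_distance_matrix(sub.values.T), method=method)
    sample_leaves = [sub.sample_ids[i] for i in hierarchy.leaves_list(sample_linkage)]

    coherence = math.nan
    truth = [labels.get(s, "") for s in sub.sample_ids]
    k = len(set(truth))
    if k >= 2:
        cut = hierarchy.fcluster(sample_linkage, t=k, criterion="maxclust")
        coherence = float(adjusted_rand_score(truth, cut))
    return ClusteringResult(
        gene_linkage, sample_linkage, gene_leaves, sample_leaves, method, coherence
    )


def coherence_vs_random(
    expr: ExpressionMatrix,
    group: GeneGroup,
    n_random: int,
    universe: Sequence[str],
    rng: np.random.Generator | int | None = None,
    method: str = "average",
) -> tuple[float, np.ndarray, float]:
    """Compare the group's clustering coherence against size-matched random
    gene sets drawn from ``universe`` without replacement.

    Returns (group coherence, null coherences, empirical p with the add-one
    rule).  A low p means the group's genes organize the samples by their
    labels better than random draws from the interaction universe.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    present = [g for g in group.gene_ids if g in set(expr.gene_ids)]
    size = len(present)
    universe = sorted(set(universe) & set(expr.gene_ids))
    if len(universe) < size:
        raise ValueError(
            f"universe ({len(universe)} genes) smaller than group ({size})"
        )
    observed = hierarchical_cluster(expr, group, method=method, cluster_genes=False).coherence
    null = np.empty(n_random)
    for i in range(n_random):
        pick = list(rng.choice(universe, size=size, replace=False))
        res = hierarchical_cluster(
            expr, GeneGroup(f"random_{i}", tuple(pick)), method=method, cluster_genes=False
        )
        null[i] = res.coherence
    p = (1.0 + int((null >= observed).sum())) / (n_random + 1.0)
    return observed, null, p


def linkage_to_newick(linkage: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths
    derived from merge heights."""
    tree = hierarchy.to_tree(linkage)

    def fmt(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"


def plot_heatmap(
    expr: ExpressionMatrix,
    result: ClusteringResult,
    path: str,
    cmap: str = "RdBu_r",
) -> None:
    """Expression heatmap with rows/columns in dendrogram leaf order."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = expr.values.loc[result.gene_leaves, result.sample_leaves]
    fig, ax = plt.subplots(figsize=(max(4, data.shape[1] / 6), max(4, data.shape[0] / 8)))
    vmax = np.nanpercentile(np.abs(data.to_numpy()), 98) or 1.0
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(
        [f"{s} ({expr.sample_labels.get(s, '')})" for s in result.sample_leaves],
        rotation=90, fontsize=5,
    )
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels(result.gene_leaves, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# global test


def global_test_q(expr_subset: np.ndarray, outcome: np.ndarray) -> float:
    """Observed global-test statistic for an n-samples x m-genes matrix and a
    binary outcome vector.

    Genes are centered across samples internally, so Q is invariant to adding
    a constant to any gene and to gene order; duplicating every gene leaves Q
    unchanged because of the 1/m normalization.
    """
    X = np.asarray(expr_subset, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape}, outcome {y.shape}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class")
    mu = y.mean()
    e = y - mu
    Xc = X - X.mean(axis=0)
    m = X.shape[1]
    z = Xc.T @ e  # per-gene covariance with the residual, up to 1/n
    return float(z @ z / m / (mu * (1.0 - mu)))


def global_test_permutation(
    expr_subset: np.ndarray,
    outcome: np.ndarray,
    B: int = 999,
    rng: np.random.Generator | int | None = None,
    group: str = "group",
    n_genes: int | None = None,
) -> GlobalTestResult:
    """Permutation inference for the global test.

    The outcome vector is permuted B times; expected_Q and sd_Q summarize the
    permutation distribution, and p uses the add-one rule (lower bound
    1/(B+1)).
    """
    if B < 99:
        raise ValueError("B must be >= 99")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(expr_subset, dtype=float)
    y = np.asarray(outcome, dtype=float)
    q_obs = global_test_q(X, y)

    mu = y.mean()
    Xc = X - X.mean(axis=0)
    m = X.shape[1]
    # permuting y is equivalent to permuting the residual vector
    perm = np.stack([rng.permutation(y) for _ in range(B)]) - mu  # B x n
    Z = perm @ Xc  # B x m
    q_perm = (Z**2).sum(axis=1) / m / (mu * (1.0 - mu))

    p = (1.0 + int((q_perm >= q_obs).sum())) / (B + 1.0)
    return GlobalTestResult(
        group=group,
        n_genes=n_genes if n_genes is not None else m,
        n_tested=m,
        Q=q_obs,
        expected_Q=float(q_perm.mean()),
        sd_Q=float(q_perm.std(ddof=1)),
        p_value=p,
    )


def global_test_report(
    expr: ExpressionMatrix,
    groups: Sequence[GeneGroup],
    positive_label: str,
    B: int = 999,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Run the global test for each gene group against a binary label.

    Emits the report schema: Gene Group, Genes, Tested, Statistic Q,
    Expected Q, sd of Q, p-value.  Groups with fewer than one tested gene or a
    single-class outcome are reported with NaN statistics and a warning.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = np.array([1.0 if expr.sample_labels.get(s) == positive_label else 0.0
                  for s in expr.sample_ids])
    rows = []
    for grp in groups:
        sub = expr.subset_genes(grp.gene_ids)
        if sub.shape[0] == 0 or len(np.unique(y)) < 2:
            log.warning("global test: group %s untestable", grp.name)
            rows.append(GlobalTestResult(grp.name, len(grp.gene_ids), sub.shape[0],
                                         math.nan, math.nan, math.nan, math.nan))
            continue
        res = global_test_permutation(
            sub.values.to_numpy().T, y, B=B, rng=rng,
            group=grp.name, n_genes=len(grp.gene_ids),
        )
        rows.append(res)
    return pd.DataFrame(
        {
            "Gene Group": [r.group for r in rows],
            "Genes": [r.n_genes for r in rows],
            "Tested": [r.n_tested for r in rows],
            "Statistic Q": [r.Q for r in rows],
            "Expected Q": [r.expected_Q for r in rows],
            "sd of Q": [r.sd_Q for r in rows],
            "p-value": [r.p_value for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# gene groups


def build_gene_groups(
    window_genes: Mapping[str, Iterable[str]],
    network_genes: Mapping[str, Iterable[str]],
    hotcold_genes: Mapping[str, Iterable[str]],
) -> list[GeneGroup]:
    """Assemble the seven standard gene groups from upstream outputs.

    Inputs are keyed by tissue compartment ("epithelium" / "stroma"):
    marker-window gene sets, signaling-network gene sets, and the hot/cold-
    window subset of each network.  Emits, in order: the two window groups,
    the two network groups, the network intersection, and the two hot/cold
    network subsets.  Empty networks yield empty groups with a warning.
    """
    def _sorted(m: Mapping[str, Iterable[str]], k: str) -> tuple[str, ...]:
        return tuple(sorted(set(m.get(k, ()))))

    ew, sw = _sorted(window_genes, "epithelium"), _sorted(window_genes, "stroma")
    en, sn = _sorted(network_genes, "epithelium"), _sorted(network_genes, "stroma")
    groups = [
        GeneGroup("epithelium_window", ew, "marker_window"),
        GeneGroup("stroma_window", sw, "marker_window"),
        GeneGroup("epithelium_network", en, "network"),
        GeneGroup("stroma_network", sn, "network"),
        GeneGroup("network_intersection", tuple(sorted(set(en) & set(sn))),
                  "network_intersection"),
        GeneGroup("epithelium_network_hotcold", _sorted(hotcold_genes, "epithelium"),
                  "network_hotcold"),
        GeneGroup("stroma_network_hotcold", _sorted(hotcold_genes, "stroma"),
                  "network_hotcold"),
    ]
    for grp in groups:
        if not grp.gene_ids:
            log.warning("gene group %s is empty", grp.name)
    return groups
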