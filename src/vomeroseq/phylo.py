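"""Correlation analysis and bootstrap-supported expression dendrograms.

Expression-trait trees are built by average-linkage (UPGMA) clustering
of ``1 - Spearman rho`` distances between per-strain mean expression
profiles, with genes as observations.  Node support comes from
resampling genes with replacement: the bootstrap probability (bp) of an
internal node is the fraction of bootstrap trees containing the same set
of leaves beneath a node, and the approximately-unbiased value (au)
corrects bp for its known size bias by multiscale bootstrapping —
resampling at several sample sizes ``ceil(r * n_genes)`` and fitting the
probit-transformed bp against the scale:

    z(r) = Phi^{-1}(1 - bp(r)) = v * sqrt(r) + c / sqrt(r)
    au   = 1 - Phi(v - c)

where ``v`` estimates the signed distance of the data from the region
boundary of the hypothesis and ``c`` its curvature.  The fit is weighted
least squares with binomial weights ``B * phi(z)^2 / (bp * (1 - bp))``.

The average-linkage agglomeration is implemented here (rather than
delegated) so ties break deterministically to the pair containing the
lexicographically smallest leaf label.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DendroNode", "spearman_matrix", "strain_mean_profiles",
           "hclust_average", "bootstrap_support", "au_support",
           "correlation_cluster_report", "cut_tree"]


@dataclass
class DendroNode:
    """A node of an ultrametric average-linkage dendrogram."""

    height: float = 0.0
    children: tuple = ()
    label: str | None = None
    bp: float | None = None
    au: float | None = None
    au_degenerate: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaves(self) -> tuple:
        if self.is_leaf:
            return (self.label,)
        out = []
        for ch in self.children:
            out.extend(ch.leaves)
        return tuple(sorted(out))

    def internal_nodes(self):
        if not self.is_leaf:
            yield self
            for ch in self.children:
                yield from ch.internal_nodes()

    def to_newick(self, support: str | None = "bp") -> str:
        return self._newick(self.height, support) + ";"

    def _newick(self, parent_height: float, support) -> str:
        # ultrametric: leaf depth = height / 2 on each side of a merge
        branch = max(parent_height - self.height, 0.0) / 2.0
        if self.is_leaf:
            return f"{self.label}:{branch:.6g}"
        inner = ",".join(ch._newick(self.height, support) for ch in self.children)
        label = ""
        if support == "bp" and self.bp is not None:
            label = f"{self.bp:.3f}"
        elif support == "aubp" and self.bp is not None:
            au = self.au if self.au is not None else float("nan")
            label = f"{au:.3f}/{self.bp:.3f}"
        return f"({inner}){label}:{branch:.6g}"


def spearman_matrix(expr: pd.DataFrame, gene_sets=None) -> pd.DataFrame:
    """Gene x gene Spearman correlation of per-sample expression.

    Average ranks for ties; constant genes (zero rank variance) get NaN
    correlations and are reported with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("Spearman correlation needs >= 3 samples")
    genes = list(expr.index)
    if gene_sets is not None:
        wanted = [g for gs in gene_sets for g in gs]
        seen = set()
        genes = [g for g in wanted if not (g in seen or seen.add(g))]
    x = expr.loc[genes].to_numpy(dtype=float)
    ranks = stats.rankdata(x, axis=1)
    constant = ranks.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s); correlations set to NaN")
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
    return pd.DataFrame(rho, index=genes, columns=genes)


def strain_mean_profiles(norm: pd.DataFrame, meta: pd.DataFrame,
                         genes=None) -> pd.DataFrame:
    """Genes x strains matrix of mean normalized expression."""
    m = meta.set_index("sample_id")
    sub = norm if genes is None else norm.loc[list(genes)]
    out = {}
    for strain in sorted(set(m["strain"])):
        cols = [s for s in norm.columns if m.loc[s, "strain"] == strain]
        out[strain] = sub[cols].mean(axis=1)
    return pd.DataFrame(out)


def _corr_distance(profiles: np.ndarray) -> np.ndarray:
    """1 - Spearman rho between columns; NaN when a column is constant."""
    ranks = stats.rankdata(profiles, axis=0)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks.T)
    rho = np.atleast_2d(rho)
    if (sd == 0).any():
        rho[sd == 0, :] = np.nan
        rho[:, sd == 0] = np.nan
    return 1.0 - rho


def hclust_average(dist: pd.DataFrame) -> DendroNode:
    """Average-linkage (UPGMA) agglomeration of a square distance matrix.

    Ties break to the candidate pair containing the lexicographically
    smallest leaf label (then the smallest partner), making the tree
    deterministic for any input.
    """
    if dist.shape[0] != dist.shape[1] or list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix must be square with matching labels")
    d = dist.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    labels = [str(x) for x in dist.index]
    nodes = {i: DendroNode(label=labels[i]) for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    minleaf = {i: labels[i] for i in range(len(labels))}
    dmat = {frozenset((i, j)): d[i, j]
            for i in range(len(labels)) for j in range(i + 1, len(labels))}
    active = set(nodes)
    next_id = len(labels)
    while len(active) > 1:
        best_key, best = None, None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                dij = dmat[frozenset((i, j))]
                key = (dij, *sorted((minleaf[i], minleaf[j])))
                if best is None or key < best:
                    best, best_key = key, (i, j)
        i, j = best_key
        a, b = sorted((i, j), key=lambda k: minleaf[k])
        new = DendroNode(height=best[0], children=(nodes[a], nodes[b]))
        active -= {i, j}
        for k in active:
            dk = (sizes[i] * dmat[frozenset((i, k))]
                  + sizes[j] * dmat[frozenset((j, k))]) / (sizes[i] + sizes[j])
            dmat[frozenset((next_id, k))] = dk
        nodes[next_id] = new
        sizes[next_id] = sizes[i] + sizes[j]
        minleaf[next_id] = min(minleaf[i], minleaf[j])
        active.add(next_id)
        next_id += 1
    return nodes[next_id - 1]


def _tree_clusters(node: DendroNode) -> set:
    return {frozenset(n.leaves) for n in node.internal_nodes()}


def _bootstrap_counts(profiles: np.ndarray, labels, m: int, n_boot: int,
                      rng: np.random.Generator):
    """Cluster counts over ``n_boot`` gene resamples of size ``m``."""
    n = profiles.shape[0]
    counter: Counter = Counter()
    valid = 0
    idx_cols = pd.Index(labels)
    for _ in range(n_boot):
        idx = rng.integers(0, n, m)
        dm = _corr_distance(profiles[idx])
        if np.isnan(dm).any():
            continue
        tree = hclust_average(pd.DataFrame(dm, index=idx_cols, columns=idx_cols))
        counter.update(_tree_clusters(tree))
        valid += 1
    return counter, valid


def bootstrap_support(profiles: pd.DataFrame, n_boot: int = 1000,
                      seed: int = 0) -> DendroNode:
    """Tree over profile columns with bootstrap probabilities per node.

    Genes (rows) are resampled with replacement; the bp of a node is the
    fraction of bootstrap trees containing the identical leaf set.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if profiles.shape[0] < 10:
        warnings.warn("fewer than 10 genes: bootstrap support will be unstable")
    labels = list(profiles.columns)
    x = profiles.to_numpy(dtype=float)
    base = hclust_average(pd.DataFrame(_corr_distance(x), index=labels, columns=labels))
    rng = np.random.default_rng(seed)
    counter, valid = _bootstrap_counts(x, labels, x.shape[0], n_boot, rng)
    for node in base.internal_nodes():
        node.bp = counter[frozenset(node.leaves)] / valid if valid else np.nan
    return base


DEFAULT_SCALES = (0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)


def au_support(profiles: pd.DataFrame, scales=DEFAULT_SCALES,
               n_boot_per_scale: int = 1000, seed: int = 0) -> DendroNode:
    """Multiscale bootstrap: au and bp per internal node.

    Runs the gene bootstrap at each relative sample size in ``scales``
    and fits the probit regression described in the module docstring.
    Nodes whose bp is 0 or 1 at every scale are degenerate: au is set to
    that bp and flagged.
    """
    scales = tuple(float(r) for r in scales)
    if len(scales) < 3 or min(scales) >= 1.0 or max(scales) <= 1.0:
        raise ValueError("need >= 3 scale factors spanning values below and above 1")
    if 1.0 not in scales:
        raise ValueError("scales must include 1.0 so bp is defined at the data size")
    labels = list(profiles.columns)
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    base = hclust_average(pd.DataFrame(_corr_distance(x), index=labels, columns=labels))
    rng = np.random.default_rng(seed)
    per_scale = {}
    for r in scales:
        counter, valid = _bootstrap_counts(x, labels, int(np.ceil(r * n)),
                                           n_boot_per_scale, rng)
        per_scale[r] = (counter, valid)
    for node in base.internal_nodes():
        key = frozenset(node.leaves)
        bps = {r: (per_scale[r][0][key] / per_scale[r][1] if per_scale[r][1] else np.nan)
               for r in scales}
        node.bp = bps[1.0]
        raw = np.array([bps[r] for r in scales])
        if np.all(raw >= 1.0) or np.all(raw <= 0.0):
            node.au = float(node.bp)
            node.au_degenerate = True
            continue
        b = n_boot_per_scale
        clipped = np.clip(raw, 1.0 / (b + 1), b / (b + 1.0))
        z = stats.norm.ppf(1.0 - clipped)
        sq = np.sqrt(np.array(scales))
        design = np.column_stack([sq, 1.0 / sq])
        w = b * stats.norm.pdf(z) ** 2 / (clipped * (1.0 - clipped))
        wsqrt = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * wsqrt[:, None], z * wsqrt, rcond=None)
        v, c = coef
        node.au = float(1.0 - stats.norm.cdf(v - c))
    return base


def cut_tree(node: DendroNode, k: int) -> list:
    """Cut into ``k`` groups by repeatedly splitting the tallest cluster."""
    groups = [node]
    while len(groups) < k:
        splittable = [g for g in groups if not g.is_leaf]
        if not splittable:
            break
        tallest = max(splittable, key=lambda g: g.height)
        groups.remove(tallest)
        groups.extend(tallest.children)
    return [list(g.leaves) for g in groups]


def correlation_cluster_report(corr: pd.DataFrame, lnc_ids, receptor_ids,
                               n_receptor_clusters: int = 2) -> pd.DataFrame:
    """Label each lncRNA by the sign of its mean correlation to each
    average-linkage cluster of receptor genes."""
    lnc_ids, receptor_ids = list(lnc_ids), list(receptor_ids)
    rec_corr = corr.loc[receptor_ids, receptor_ids]
    if len(receptor_ids) > 1:
        tree = hclust_average(1.0 - rec_corr)
        clusters = cut_tree(tree, min(n_receptor_clusters, len(receptor_ids)))
    else:
        clusters = [receptor_ids]
    rows = []
    for lnc in lnc_ids:
        for ci, members in enumerate(clusters):
            mean_rho = float(corr.loc[lnc, members].mean())
            rows.append({
                "lnc": lnc, "receptor_cluster": ci,
                "receptors": ",".join(members),
                "mean_rho": mean_rho,
                "sign": "positive" if mean_rho >= 0 else "negative",
            })
    return pd.DataFrame(rows)
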