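import numpy as np
import pandas as pd
import pytest

from vomeroseq import phylo as PH
from vomeroseq.simulate import simulate_strain_profiles


# ------------------------------------------------------------ spearman

def brute_force_spearman(x, y):
    """Independent oracle: average ranks by hand, then Pearson by formula."""
    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def test_self_correlation_and_rank_invariance():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.random((3, 12)), index=["a", "b", "c"])
    expr.loc["b"] = np.exp(3 * expr.loc["a"])        # strictly monotone in a
    corr = PH.spearman_matrix(expr)
    assert corr.loc["a", "a"] == 1.0
    assert corr.loc["a", "b"] == pytest.approx(1.0)


def test_spearman_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.integers(0, 8, size=(10, 12)).astype(float),
                        index=[f"g{i}" for i in range(10)])
    corr = PH.spearman_matrix(expr)
    for i in range(10):
        for j in range(10):
            expected = brute_force_spearman(expr.iloc[i], expr.iloc[j])
            assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)


def test_constant_gene_flagged_as_missing():
    expr = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "ok"],
                        dtype=float)
    with pytest.warns(UserWarning, match="constant"):
        corr = PH.spearman_matrix(expr)
    assert np.isnan(corr.loc["flat", "ok"])


# ------------------------------------------------------------ average linkage

def naive_average_linkage(dist):
    """Independent O(n^3) oracle: cluster distances recomputed from the
    original matrix as the mean over all cross pairs."""
    labels = list(dist.index)
    d = dist.to_numpy(float)
    clusters = [frozenset([i]) for i in range(len(labels))]
    merges = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                val = np.mean([d[x, y] for x in clusters[ai] for y in clusters[bi]])
                if best is None or val < best[0] - 1e-15:
                    best = (val, ai, bi)
        val, ai, bi = best
        merged = clusters[ai] | clusters[bi]
        merges.append((frozenset(labels[i] for i in merged), val))
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)] + [merged]
    return merges


def test_identical_profiles_merge_first():
    labels = ["a", "b", "c", "d"]
    d = np.array([[0, 5, 0.0, 6], [5, 0, 5, 3], [0.0, 5, 0, 6], [6, 3, 6, 0]],
                 float)
    tree = PH.hclust_average(pd.DataFrame(d, index=labels, columns=labels))
    first = min(tree.internal_nodes(), key=lambda n: n.height)
    assert set(first.leaves) == {"a", "c"} and first.height == 0.0


def test_two_block_structure_recovered():
    labels = ["A", "B", "C", "D"]
    d = np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]], float)
    tree = PH.hclust_average(pd.DataFrame(d, index=labels, columns=labels))
    clusters = {frozenset(n.leaves) for n in tree.internal_nodes()}
    assert frozenset({"A", "B"}) in clusters and frozenset({"C", "D"}) in clusters


def test_average_linkage_matches_naive_oracle():
    rng = np.random.default_rng(7)
    for trial in range(4):
        n = 8
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"L{i}" for i in range(n)]
        dist = pd.DataFrame(d, index=labels, columns=labels)
        tree = PH.hclust_average(dist)
        got = sorted(((frozenset(node.leaves), node.height)
                      for node in tree.internal_nodes()), key=lambda t: t[1])
        expected = sorted(naive_average_linkage(dist), key=lambda t: t[1])
        for (ga, ha), (gb, hb) in zip(got, expected):
            assert ga == gb and ha == pytest.approx(hb, abs=1e-10)


def test_average_linkage_matches_scipy():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    rng = np.random.default_rng(8)
    n = 10
    m = rng.random((n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"L{i}" for i in range(n)]
    tree = PH.hclust_average(pd.DataFrame(d, index=labels, columns=labels))
    heights = sorted(node.height for node in tree.internal_nodes())
    z = linkage(squareform(d), method="average")
    assert np.allclose(heights, sorted(z[:, 2]), atol=1e-10)


def test_asymmetric_matrix_rejected():
    d = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"],
                     dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        PH.hclust_average(d)


# ------------------------------------------------------------ bootstrap / au

def test_planted_outgroup_recovers_high_bp():
    profiles, true_splits = simulate_strain_profiles(seed=1, n_genes=200)
    tree = PH.bootstrap_support(profiles, n_boot=500, seed=1)
    by_split = {frozenset(n.leaves): n.bp for n in tree.internal_nodes()}
    for split in true_splits:
        assert split in by_split and by_split[split] >= 0.95


def test_bootstrap_deterministic_given_seed():
    profiles, _ = simulate_strain_profiles(seed=2, n_genes=60)
    a = PH.bootstrap_support(profiles, n_boot=200, seed=5)
    b = PH.bootstrap_support(profiles, n_boot=200, seed=5)
    assert [n.bp for n in a.internal_nodes()] == [n.bp for n in b.internal_nodes()]


def test_bootstrap_invariant_to_leaf_order():
    profiles, _ = simulate_strain_profiles(seed=3, n_genes=80)
    a = PH.bootstrap_support(profiles, n_boot=200, seed=9)
    b = PH.bootstrap_support(profiles[list(profiles.columns)[::-1]],
                             n_boot=200, seed=9)
    bp_a = {frozenset(n.leaves): n.bp for n in a.internal_nodes()}
    bp_b = {frozenset(n.leaves): n.bp for n in b.internal_nodes()}
    assert set(bp_a) == set(bp_b)
    for key in bp_a:
        assert abs(bp_a[key] - bp_b[key]) < 0.08    # same law, fresh resamples
        assert 0.0 <= bp_a[key] <= 1.0


def test_pure_noise_rarely_reaches_high_support():
    rng = np.random.default_rng(0)
    max_bps = []
    for seed in range(30):
        profiles = pd.DataFrame(rng.lognormal(4, 1, size=(80, 4)),
                                columns=["B6", "129", "SJL", "SWR"])
        tree = PH.bootstrap_support(profiles, n_boot=200, seed=seed)
        bps = [n.bp for n in tree.internal_nodes() if len(n.leaves) < 4]
        max_bps.append(max(bps))
    assert np.median(max_bps) < 0.95


def test_au_degenerate_node_equals_bp():
    profiles, true_splits = simulate_strain_profiles(seed=4, n_genes=400)
    tree = PH.au_support(profiles, n_boot_per_scale=200, seed=4)
    for node in tree.internal_nodes():
        if frozenset(node.leaves) in true_splits and node.bp == 1.0:
            assert node.au == 1.0
    again = PH.au_support(profiles, n_boot_per_scale=200, seed=4)
    assert [n.au for n in tree.internal_nodes()] == [n.au for n in again.internal_nodes()]


def test_au_close_to_or_above_bp_on_planted_split():
    profiles, true_splits = simulate_strain_profiles(seed=6, n_genes=150)
    tree = PH.au_support(profiles, n_boot_per_scale=400, seed=6)
    by_split = {frozenset(n.leaves): n for n in tree.internal_nodes()}
    for split in true_splits:
        node = by_split[split]
        assert node.au >= node.bp - 0.05


def test_au_scale_preconditions():
    profiles, _ = simulate_strain_profiles(seed=7, n_genes=50)
    with pytest.raises(ValueError, match="scale"):
        PH.au_support(profiles, scales=(1.0, 1.1, 1.2), n_boot_per_scale=200)


# ------------------------------------------------------------ newick & clusters

def test_newick_has_au_bp_labels():
    profiles, _ = simulate_strain_profiles(seed=8, n_genes=100)
    tree = PH.au_support(profiles, n_boot_per_scale=200, seed=8)
    text = tree.to_newick(support="aubp")
    assert text.endswith(";") and "/" in text
    import dendropy
    dendropy.Tree.get(data=text, schema="newick")


def test_correlation_cluster_report_recovers_planted_signs(sim_small):
    from vomeroseq import de as D
    norm = D.estimate_size_factors(sim_small.counts)
    blocks = sim_small.truth.corr_blocks
    lnc = [g for b in blocks for g in b["lnc"]]
    rcpt = [g for b in blocks for g in b["receptors"]]
    corr = PH.spearman_matrix(norm.normalized, [lnc, rcpt])
    report = PH.correlation_cluster_report(corr, lnc, rcpt)
    pos_block, anti_block = blocks
    for lnc_gene in pos_block["lnc"]:
        sub = report[(report["lnc"] == lnc_gene)
                     & report["receptors"].str.contains(pos_block["receptors"][0])]
        assert (sub["sign"] == "positive").all()
    anti = report[(report["lnc"] == "LncAnti")
                  & report["receptors"].str.contains("RcptAnti")]
    assert (anti["sign"] == "negative").all()


def test_single_gene_sets_give_trivial_report():
    corr = pd.DataFrame([[1.0, -0.8], [-0.8, 1.0]],
                        index=["lnc1", "r1"], columns=["lnc1", "r1"])
    report = PH.correlation_cluster_report(corr, ["lnc1"], ["r1"])
    assert len(report) == 1 and report.iloc[0]["sign"] == "negative"
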