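import numpy as np
import pandas as pd
import pytest

from vomeroseq import de as D
from vomeroseq.simulate import SimParams, simulate_counts


def _nb_matrix(seed=0, n=500, samples=8, mean=100.0, alpha=0.3):
    rng = np.random.default_rng(seed)
    r = 1 / alpha
    x = rng.negative_binomial(r, r / (r + mean), size=(n, samples))
    return pd.DataFrame(x.astype(np.int64), index=[f"g{i}" for i in range(n)],
                        columns=[f"s{i}" for i in range(samples)])


def _meta(columns, groups):
    return pd.DataFrame({"sample_id": list(columns), "strain": groups,
                         "sex": ["male", "female"] * (len(columns) // 2),
                         "replicate": 1})


# ------------------------------------------------------------ size factors

def test_identical_samples_get_unit_size_factors():
    counts = pd.DataFrame({"s1": [10, 20], "s2": [10, 20], "s3": [10, 20]},
                          index=["gA", "gB"])
    sf = D.estimate_size_factors(counts).size_factors
    assert np.allclose(sf, 1.0)


def test_doubled_sample_has_double_the_factor():
    rng = np.random.default_rng(1)
    col = rng.integers(1, 500, size=200)
    counts = pd.DataFrame({f"s{i}": col for i in range(4)},
                          index=[f"g{i}" for i in range(200)])
    counts["s0"] = counts["s0"] * 2
    sf = D.estimate_size_factors(counts).size_factors
    ratios = sf["s0"] / sf[["s1", "s2", "s3"]]
    assert np.allclose(ratios, 2.0, rtol=1e-10)


def test_size_factors_match_brute_force_median_of_ratios():
    counts = _nb_matrix(seed=2, n=500, samples=8)
    sf = D.estimate_size_factors(counts).size_factors.to_numpy()
    # independent oracle: literal median-of-ratios over all-positive genes
    x = counts.to_numpy(dtype=float)
    pos = (x > 0).all(axis=1)
    geo = np.exp(np.log(x[pos]).mean(axis=1))
    ratios = x[pos] / geo[:, None]
    oracle = np.median(ratios, axis=0)
    oracle = oracle / np.exp(np.log(oracle).mean())
    assert np.allclose(sf, oracle, atol=1e-12)


def test_rescaling_one_sample_scales_factor_ratios_by_c():
    counts = _nb_matrix(seed=3, n=300, samples=6) + 1
    base = D.estimate_size_factors(counts)
    scaled = counts.copy()
    scaled["s2"] = scaled["s2"] * 3
    res = D.estimate_size_factors(scaled)
    ratio_base = base.size_factors["s2"] / base.size_factors["s0"]
    ratio_scaled = res.size_factors["s2"] / res.size_factors["s0"]
    assert np.isclose(ratio_scaled, 3 * ratio_base, rtol=1e-10)
    # normalized counts unchanged up to one common positive scalar
    f = res.normalized / base.normalized
    assert np.isclose(f.to_numpy().std() / f.to_numpy().mean(), 0.0, atol=1e-10)


def test_no_universally_detected_gene_is_an_error():
    counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=["gA", "gB"])
    with pytest.raises(ValueError, match="pseudo-reference"):
        D.estimate_size_factors(counts)


# ------------------------------------------------------------ dispersion

def test_constant_gene_gets_zero_dispersion():
    counts = pd.DataFrame({f"s{i}": [50, 7] for i in range(6)}, index=["gA", "gB"])
    meta = _meta(counts.columns, ["A"] * 3 + ["B"] * 3)
    norm = D.NormalizationResult(pd.Series(1.0, index=counts.columns),
                                 counts.astype(float))
    disp = D.estimate_dispersion(norm, meta, group_cols=("strain",))
    assert disp.alpha["gA"] == 0.0 and disp.alpha["gB"] == 0.0


def test_poisson_gene_dispersion_near_zero():
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(rng.poisson(100.0, size=(1, 200)).astype(np.int64),
                          index=["gA"], columns=[f"s{i}" for i in range(200)])
    meta = _meta(counts.columns, ["A"] * 200)
    norm = D.NormalizationResult(pd.Series(1.0, index=counts.columns),
                                 counts.astype(float))
    disp = D.estimate_dispersion(norm, meta, group_cols=("strain",))
    assert 0.0 <= disp.alpha["gA"] <= 0.05


def test_nb_dispersion_recovered_across_seeds():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        r = 1 / 0.5
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + 100.0), size=(1, 200)).astype(np.int64),
            index=["gA"], columns=[f"s{i}" for i in range(200)])
        meta = _meta(counts.columns, ["A"] * 200)
        norm = D.NormalizationResult(pd.Series(1.0, index=counts.columns),
                                     counts.astype(float))
        alpha = D.estimate_dispersion(norm, meta, group_cols=("strain",)).alpha["gA"]
        hits += 0.35 <= alpha <= 0.65
    assert hits >= 18


def test_single_replicate_dispersion_is_an_error():
    counts = _nb_matrix(seed=0, n=5, samples=4)
    meta = _meta(counts.columns, ["A", "B", "C", "D"])
    norm = D.estimate_size_factors(counts)
    with pytest.raises(ValueError, match="unidentifiable"):
        D.estimate_dispersion(norm, meta, group_cols=("strain",))


# ------------------------------------------------------------ Wald test

def test_planted_lfc_recovered(two_group_counts):
    counts, meta = two_group_counts
    norm = D.NormalizationResult(pd.Series(1.0, index=counts.columns),
                                 counts.astype(float))
    disp = D.estimate_dispersion(norm, meta, group_cols=("strain",))
    tab = D.wald_test(norm, meta, ("A", "B"), disp)
    assert 1.7 <= tab["lfc"].mean() <= 2.3


def test_null_type_one_error_calibrated():
    d = simulate_counts(SimParams(seed=42, n_genes=5000, lfc_magnitude=0.0))
    norm = D.estimate_size_factors(d.counts)
    disp = D.estimate_dispersion(norm, d.meta)
    tab = D.wald_test(norm, d.meta, ("B6", "SWR"), disp)
    frac = (tab["pvalue"] < 0.01).mean()
    assert 0.005 <= frac <= 0.02


def test_all_zero_group_gives_finite_directional_lfc():
    counts = pd.DataFrame({"s0": [0], "s1": [0], "s2": [400], "s3": [410]},
                          index=["gA"])
    counts["pad"] = 5  # keep a universally detected gene for normalization
    counts = pd.concat([counts, pd.DataFrame(
        {"s0": [50], "s1": [55], "s2": [45], "s3": [60], "pad": [50]}, index=["gB"])])
    counts = counts[["s0", "s1", "s2", "s3"]]
    meta = _meta(counts.columns, ["A", "A", "B", "B"])
    norm = D.NormalizationResult(pd.Series(1.0, index=counts.columns),
                                 counts.astype(float))
    disp = D.estimate_dispersion(norm, meta, group_cols=("strain",))
    tab = D.wald_test(norm, meta, ("A", "B"), disp)
    assert np.isfinite(tab.loc["gA", "lfc"]) and tab.loc["gA", "lfc"] < 0
    assert tab.loc["gA", "pvalue"] < 0.05


def test_swapping_contrast_negates_lfc_and_preserves_p(two_group_counts):
    counts, meta = two_group_counts
    norm = D.NormalizationResult(pd.Series(1.0, index=counts.columns),
                                 counts.astype(float))
    disp = D.estimate_dispersion(norm, meta, group_cols=("strain",))
    ab = D.wald_test(norm, meta, ("A", "B"), disp)
    ba = D.wald_test(norm, meta, ("B", "A"), disp)
    assert np.allclose(ab["lfc"], -ba["lfc"])
    assert np.allclose(ab["pvalue"], ba["pvalue"])


def test_absent_group_rejected(two_group_counts):
    counts, meta = two_group_counts
    norm = D.estimate_size_factors(counts)
    disp = D.estimate_dispersion(norm, meta, group_cols=("strain",))
    with pytest.raises(ValueError, match="absent"):
        D.wald_test(norm, meta, ("A", "Z"), disp)


# ------------------------------------------------------------ BH FDR

def test_bh_single_p_is_itself():
    assert D.bh_fdr([0.03]) == pytest.approx([0.03])


def test_bh_hand_computed_step_up():
    assert np.allclose(D.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_brute_force_definition_exactly():
    rng = np.random.default_rng(11)
    p = rng.random(400)
    q = D.bh_fdr(p)
    # oracle: q_i = min_{j >= i} n * p_(j) / j on the sorted vector
    order = np.argsort(p)
    n = len(p)
    sorted_q = np.minimum.accumulate((n * p[order] / np.arange(1, n + 1))[::-1])[::-1]
    oracle = np.empty(n)
    oracle[order] = np.minimum(sorted_q, 1.0)
    assert np.array_equal(q, oracle)
    assert (q >= p).all()


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(12)
    p = rng.random(300)
    assert np.allclose(D.bh_fdr(p), multipletests(p, method="fdr_bh")[1],
                       atol=1e-12)


def test_bh_rejects_out_of_range_p():
    with pytest.raises(ValueError):
        D.bh_fdr([0.5, 1.2])


# ------------------------------------------------------------ outlier filter

def test_outlier_gene_filtered_homogeneous_kept():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.poisson(100, size=(52, 8)).astype(np.int64),
                          index=["outlier", "clean"] + [f"bg{i}" for i in range(50)],
                          columns=[f"s{i}" for i in range(8)])
    counts.loc["outlier", "s0"] = 100 * 100
    meta = _meta(counts.columns, ["A"] * 4 + ["B"] * 4)
    norm = D.NormalizationResult(pd.Series(1.0, index=counts.columns),
                                 counts.astype(float))
    disp = D.estimate_dispersion(norm, meta, group_cols=("strain",))
    flags = D.independent_filter(norm, meta, disp)
    assert bool(flags["outlier"]) and not bool(flags["clean"])
    off = D.independent_filter(norm, meta, disp, enabled=False)
    assert not off.any()


# ------------------------------------------------------------ classification

def test_classify_de_or_semantics_and_missing_contrast():
    idx = ["gA", "gB"]
    def tab(de):
        return pd.DataFrame({"de": de}, index=idx)
    tables = {("A", "B"): tab([True, False]), ("A", "C"): tab([False, False]),
              ("B", "C"): tab([False, False])}
    flags = D.classify_de(tables, ["A", "B", "C"])
    assert bool(flags["gA"]) and not bool(flags["gB"])
    with pytest.raises(ValueError, match="missing"):
        D.classify_de({("A", "B"): tab([True, False])}, ["A", "B", "C"])


def test_sub_threshold_fold_change_not_flagged():
    rng = np.random.default_rng(9)
    # flat background plus one gene at FC 1.9: significant but under 2-fold
    mu = np.full((51, 8), 1000.0)
    mu[0, :4] *= 1.9
    counts = pd.DataFrame(rng.poisson(mu).astype(np.int64),
                          columns=[f"s{i}" for i in range(8)])
    counts.index = [f"g{i}" for i in range(51)]
    meta = _meta(counts.columns, ["A"] * 4 + ["B"] * 4)
    res = D.run_pairwise_de(counts, meta, dispersion_group_cols=("strain",),
                            filter_outliers=False)
    tab = res.tables[("A", "B")]
    assert tab.loc["g0", "qvalue"] < 0.05          # detected as significant
    assert abs(tab.loc["g0", "lfc"]) < 1.0         # but under the fold threshold
    assert not res.de.any()


def test_planted_truth_recovery_sensitivity_and_fdp():
    d = simulate_counts(SimParams(seed=1, n_genes=4000, n_hotspots=4,
                                  n_chromosomes=2))
    res = D.run_pairwise_de(d.counts, d.meta)
    called = set(res.de.index[res.de])
    planted = d.truth.de_genes
    tp = len(called & planted)
    assert tp / len(planted) >= 0.8
    assert (len(called) - tp) / max(len(called), 1) <= 0.1


def test_qvalues_dominate_pvalues(sim_small):
    res = D.run_pairwise_de(sim_small.counts, sim_small.meta)
    for tab in res.tables.values():
        keep = ~tab["filtered"]
        assert (tab.loc[keep, "qvalue"] >= tab.loc[keep, "pvalue"] - 1e-12).all()


# ------------------------------------------------------------ TPM / expression

def test_tpm_single_gene_is_one_million():
    counts = pd.DataFrame({"s1": [7]}, index=["gA"])
    t = D.tpm(counts, pd.Series({"gA": 1000}))
    assert t.loc["gA", "s1"] == pytest.approx(1e6)


def test_tpm_two_genes_closed_form():
    counts = pd.DataFrame({"s1": [100, 100]}, index=["gA", "gB"])
    t = D.tpm(counts, pd.Series({"gA": 1000, "gB": 2000}))
    assert t.loc["gA", "s1"] == pytest.approx(666666.6667, abs=0.01)
    assert t.loc["gB", "s1"] == pytest.approx(333333.3333, abs=0.01)


def test_tpm_columns_conserve_one_million(sim_small):
    lengths = sim_small.annotation.set_index("gene_id")["length_bp"]
    t = D.tpm(sim_small.counts, lengths)
    assert np.allclose(t.sum(axis=0), 1e6, rtol=1e-6)


def test_tpm_zero_length_rejected():
    counts = pd.DataFrame({"s1": [1]}, index=["gA"])
    with pytest.raises(ValueError, match="length"):
        D.tpm(counts, pd.Series({"gA": 0}))


def test_expressed_flags_consistent(sim_small):
    norm = D.estimate_size_factors(sim_small.counts)
    any_flag = D.expressed_any(sim_small.counts)
    by_strain = D.expressed_by_strain(norm, sim_small.meta)
    # a gene detected in some strain must be expressed overall
    assert not (by_strain.any(axis=1) & ~any_flag).any()
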