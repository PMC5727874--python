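"""Sex-dimorphism calling and X/Y dosage-compensation accounting.

A gene counts as sexually dimorphic across strains only when the male/
female difference is consistently observed in every strain: the screen
combines per-strain fold changes into a sample-size-weighted geometric
mean ("weighted FC"), tests it with a Wald statistic, and additionally
requires the per-strain fold changes to share a direction.  A separate
within-strain analysis finds sex effects confined to individual strains
(the Simpson's-paradox cases the pooled screen would miss), and the
dosage report checks whether female X-homolog expression matches the sum
of male X- plus Y-homolog expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import de as _de

LOG2 = np.log(2.0)

__all__ = ["SexDimorphismResult", "sex_dimorphism_cross_strain",
           "within_strain_sex_de", "dosage_compensation"]


@dataclass
class SexDimorphismResult:
    table: pd.DataFrame        # per gene: weighted_fc, lfc per strain, pvalue, flags
    dimorphic: list            # genes dimorphic across all strains
    fc_threshold: float
    alpha: float


def _strain_sex_means(norm, meta):
    m = meta.set_index("sample_id")
    strains = sorted(set(m["strain"]))
    means, ns = {}, {}
    for strain in strains:
        for sex in ("male", "female"):
            cols = [s for s in norm.normalized.columns
                    if m.loc[s, "strain"] == strain and m.loc[s, "sex"] == sex]
            if not cols:
                raise ValueError(f"strain {strain!r} has no {sex} samples")
            means[(strain, sex)] = norm.normalized[cols].mean(axis=1).to_numpy()
            ns[(strain, sex)] = len(cols)
    return strains, means, ns


def sex_dimorphism_cross_strain(counts: pd.DataFrame, meta: pd.DataFrame,
                                fc_threshold: float = 2.0, alpha: float = 0.01,
                                pseudocount: float = 0.5,
                                require_consistent: bool = True,
                                variance: str = "per_strain") -> SexDimorphismResult:
    """Cross-strain male-vs-female screen on weighted fold changes.

    ``variance="per_strain"`` combines per-strain delta-method variances of
    the log fold change with the same weights as the point estimate;
    ``variance="pooled"`` instead tests all males against all females with
    a single pooled Wald test.
    """
    if variance not in ("per_strain", "pooled"):
        raise ValueError(f"unknown variance scheme {variance!r}")
    norm = _de.estimate_size_factors(counts)
    disp = _de.estimate_dispersion(norm, meta, group_cols=("strain", "sex"))
    alpha_g = np.nan_to_num(disp.alpha.to_numpy(), nan=0.0)
    strains, means, ns = _strain_sex_means(norm, meta)
    c = float(pseudocount)

    lfc_s, var_s, w = {}, {}, {}
    for strain in strains:
        mm, mf = means[(strain, "male")], means[(strain, "female")]
        nm, nf = ns[(strain, "male")], ns[(strain, "female")]
        lfc_s[strain] = np.log2((mm + c) / (mf + c))
        vm = (mm + alpha_g * mm ** 2) / nm / (mm + c) ** 2
        vf = (mf + alpha_g * mf ** 2) / nf / (mf + c) ** 2
        var_s[strain] = (vm + vf) / LOG2 ** 2
        w[strain] = nm + nf

    w_total = sum(w.values())
    wlfc = sum(w[s] * lfc_s[s] for s in strains) / w_total

    if variance == "per_strain":
        se = np.sqrt(sum((w[s] ** 2) * var_s[s] for s in strains)) / w_total
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se > 0, wlfc / np.where(se > 0, se, 1.0), 0.0)
        pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        pooled = _de.wald_test(norm, meta, ("male", "female"), disp,
                               group_col="sex", pseudocount=pseudocount)
        pvalue = pooled["pvalue"].to_numpy()

    signs = np.stack([np.sign(lfc_s[s]) for s in strains])
    consistent = (signs == signs[0]).all(axis=0) & (signs[0] != 0)
    weighted_fc = 2.0 ** np.abs(wlfc)
    flag = (weighted_fc > fc_threshold) & (pvalue < alpha)
    if require_consistent:
        flag &= consistent

    table = pd.DataFrame({"weighted_lfc": wlfc, "weighted_fc": weighted_fc,
                          "pvalue": pvalue, "consistent": consistent,
                          "dimorphic": flag}, index=counts.index)
    for s in strains:
        table[f"lfc_{s}"] = lfc_s[s]
    return SexDimorphismResult(table, list(table.index[flag]), fc_threshold, alpha)


def within_strain_sex_de(counts: pd.DataFrame, meta: pd.DataFrame,
                         fc_threshold: float = 2.0, fdr_threshold: float = 0.05,
                         pseudocount: float = 0.5):
    """Male-vs-female Wald tests run separately within each strain.

    Returns ``(per_strain_tables, combined)`` where ``combined`` lists
    genes significant in at least one strain with their strain label(s).
    """
    norm = _de.estimate_size_factors(counts)
    m = meta.set_index("sample_id")
    tables = {}
    hits: dict = {}
    for strain in sorted(set(m["strain"])):
        cols = [s for s in counts.columns if m.loc[s, "strain"] == strain]
        sub_meta = meta[meta["sample_id"].isin(cols)]
        sub_norm = _de.NormalizationResult(norm.size_factors[cols],
                                           norm.normalized[cols])
        disp = _de.estimate_dispersion(sub_norm, sub_meta, group_cols=("sex",))
        tab = _de.wald_test(sub_norm, sub_meta, ("male", "female"), disp,
                            group_col="sex", pseudocount=pseudocount)
        tab["qvalue"] = _de.bh_fdr(tab["pvalue"].to_numpy())
        tab["de"] = (np.abs(tab["lfc"]) > np.log2(fc_threshold)) & \
                    (tab["qvalue"] < fdr_threshold)
        tables[strain] = tab
        for gene in tab.index[tab["de"]]:
            hits.setdefault(gene, []).append(strain)
    combined = pd.DataFrame(
        {"gene_id": list(hits), "strains": [",".join(v) for v in hits.values()]}
    ).set_index("gene_id") if hits else pd.DataFrame(columns=["strains"])
    return tables, combined


def dosage_compensation(counts: pd.DataFrame, meta: pd.DataFrame,
                        xy_pairs) -> pd.DataFrame:
    """Per X/Y homolog pair, compare female X with male X + Y expression.

    ``ratio = female X / (male X + male Y)`` on mean normalized counts; a
    ratio near 1 indicates that the Y counterpart compensates the male's
    lower X-allele expression.  Nonzero female counts on a Y gene are a
    biological impossibility in the input and raise a validation error.
    """
    norm = _de.estimate_size_factors(counts)
    m = meta.set_index("sample_id")
    males = [s for s in counts.columns if m.loc[s, "sex"] == "male"]
    females = [s for s in counts.columns if m.loc[s, "sex"] == "female"]
    rows = []
    for x_gene, y_gene in xy_pairs:
        for g in (x_gene, y_gene):
            if g not in counts.index:
                raise ValueError(f"homolog pair gene {g!r} absent from count matrix")
        if (counts.loc[y_gene, females] > 0).any():
            raise ValueError(
                f"Y-linked gene {y_gene!r} has nonzero counts in female sample(s)"
            )
        x_f = norm.normalized.loc[x_gene, females].mean()
        x_m = norm.normalized.loc[x_gene, males].mean()
        y_m = norm.normalized.loc[y_gene, males].mean()
        combined = x_m + y_m
        rows.append({
            "x_gene": x_gene, "y_gene": y_gene,
            "x_female": x_f, "x_male": x_m, "y_male": y_m,
            "male_combined": combined,
            "ratio": x_f / combined if combined > 0 else np.inf,
        })
    return pd.DataFrame(rows)
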