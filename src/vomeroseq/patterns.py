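"""Strain-exclusive expression classification and sharing summaries.

Chemosensory receptor genes can be expressed in some inbred strains and
completely absent in others.  This module classifies each gene's
presence/absence pattern across strains, tabulates Venn-style sharing
counts over every nonempty strain subset, and summarizes per receptor
family how many DE genes lack expression in at least one strain.

Two absence rules are provided, reported side by side rather than one
being asserted as canonical: ``zero_raw`` (absent iff every raw count in
all of a strain's samples is zero — the literal reading of "completely
lacked expression") and ``mean_norm_gt1`` (absent iff the strain's mean
normalized count is <= 1, the detection threshold used elsewhere in the
pipeline).
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from ._utils import percentage
from . import de as _de

ABSENCE_RULES = ("zero_raw", "mean_norm_gt1")

__all__ = ["presence_patterns", "pattern_class", "venn_counts",
           "family_lacking_summary", "ABSENCE_RULES"]


def presence_patterns(counts: pd.DataFrame, meta: pd.DataFrame,
                      rule: str = "zero_raw",
                      norm: "_de.NormalizationResult | None" = None) -> pd.DataFrame:
    """Per-gene boolean presence per strain plus a pattern class.

    Returns a DataFrame with one boolean column per strain, an
    ``n_strains`` count and a ``pattern`` column in
    {all_strains, missing_in_k, single_strain, absent}.
    """
    if rule not in ABSENCE_RULES:
        raise ValueError(f"unknown absence rule {rule!r}; expected one of {ABSENCE_RULES}")
    m = meta.set_index("sample_id")
    strains = sorted(set(m["strain"]))
    present = {}
    if rule == "zero_raw":
        for strain in strains:
            cols = [s for s in counts.columns if m.loc[s, "strain"] == strain]
            present[strain] = (counts[cols] > 0).any(axis=1)
    else:
        if norm is None:
            norm = _de.estimate_size_factors(counts)
        flags = _de.expressed_by_strain(norm, meta, threshold=1.0)
        for strain in strains:
            present[strain] = flags[strain]
    out = pd.DataFrame(present)
    out["n_strains"] = out[strains].sum(axis=1)
    out["pattern"] = [pattern_class(n, len(strains)) for n in out["n_strains"]]
    return out


def pattern_class(n_present: int, n_strains: int) -> str:
    if n_present == 0:
        return "absent"
    if n_present == n_strains:
        return "all_strains"
    if n_present == 1:
        return "single_strain"
    return "missing_in_k"


def venn_counts(patterns: pd.DataFrame) -> pd.Series:
    """Gene counts per nonempty strain subset (2**S - 1 cells).

    The cell for a subset counts genes present in exactly that subset, so
    the cells sum to the number of genes expressed in >= 1 strain.
    """
    strains = [c for c in patterns.columns if c not in ("n_strains", "pattern")]
    counts = {}
    for r in range(1, len(strains) + 1):
        for subset in combinations(strains, r):
            mask = pd.Series(True, index=patterns.index)
            for s in strains:
                mask &= patterns[s] if s in subset else ~patterns[s]
            counts["+".join(subset)] = int(mask.sum())
    return pd.Series(counts, name="n_genes")


def family_lacking_summary(patterns: pd.DataFrame, annotation: pd.DataFrame,
                           genes=None) -> pd.DataFrame:
    """Per family: genes lacking expression in >= 1 strain, out of the total.

    ``genes`` restricts the tally (typically to DE genes).  Percentages
    are rounded half-up to 1 decimal, as printed in family summaries.
    """
    strains = [c for c in patterns.columns if c not in ("n_strains", "pattern")]
    ann = annotation.set_index("gene_id")
    idx = patterns.index if genes is None else [g for g in genes if g in patterns.index]
    rows = {}
    for gene in idx:
        family = ann.loc[gene, "family"] if gene in ann.index else None
        if not family:
            continue
        lacking = int(patterns.loc[gene, "n_strains"]) < len(strains)
        n_lack, n_tot = rows.get(family, (0, 0))
        rows[family] = (n_lack + int(lacking), n_tot + 1)
    return pd.DataFrame(
        [{"family": f, "n_lacking": nl, "n_total": nt, "pct": percentage(nl, nt)}
         for f, (nl, nt) in sorted(rows.items())]
    )
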