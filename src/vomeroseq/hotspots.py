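"""Sliding-window Poisson scan for genomic hotspots of DE genes.

Windows of ``W`` consecutive *expressed* genes (ordered by start, step 1
by default) are slid along each chromosome separately.  The DE-gene count
``k`` in a window is tested against a Poisson null with rate ``lambda =
W * genome_de_rate`` using the inclusive upper tail ``P(X >= k)``; the
genome-wide DE rate is computed over the same expressed gene set that
builds the windows.  Benjamini-Hochberg control is applied genome-wide
across all windows, significant windows sharing genes on a chromosome are
merged, and hotspot intervals span the first to the last member gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import percentage, round_half_up
from .de import bh_fdr

__all__ = ["Windows", "Hotspot", "sliding_windows", "window_poisson_test",
           "score_windows", "call_hotspots", "summarize_hotspots"]


@dataclass
class Windows:
    """Sliding windows over expressed genes, grouped by chromosome."""

    table: pd.DataFrame          # chrom, start_idx, span_start, span_end [, k, lam, p, q]
    genes_by_chrom: dict         # chrom -> np.ndarray of expressed gene ids, position order
    W: int
    step: int = 1

    def member_genes(self, row) -> np.ndarray:
        i0 = int(row["start_idx"])
        return self.genes_by_chrom[row["chrom"]][i0:i0 + self.W]


@dataclass
class Hotspot:
    chrom: str
    start: int                   # 1-based inclusive, min start over member genes
    end: int                     # max end over member genes
    genes: tuple
    n_expressed: int
    n_de: int

    @property
    def span_mb(self) -> float:
        return (self.end - self.start) / 1e6

    @property
    def pct_de(self) -> float:
        return 100.0 * self.n_de / self.n_expressed if self.n_expressed else 0.0


def sliding_windows(annotation: pd.DataFrame, expressed_ids, W: int = 25,
                    step: int = 1) -> Windows:
    """Build windows of ``W`` expressed genes per chromosome (step in genes).

    Chromosomes with fewer than ``W`` expressed genes yield no windows.
    """
    if W < 2:
        raise ValueError(f"window size W={W} must be >= 2")
    if step < 1:
        raise ValueError(f"step={step} must be >= 1")
    expressed = set(expressed_ids)
    unknown = expressed - set(annotation["gene_id"])
    if unknown:
        raise ValueError(f"expressed gene(s) absent from annotation: {sorted(unknown)[:5]}")
    ann = annotation[annotation["gene_id"].isin(expressed)].sort_values(
        ["chrom", "start", "end", "gene_id"], kind="mergesort")
    genes_by_chrom, rows = {}, []
    for chrom, sub in ann.groupby("chrom", sort=True):
        ids = sub["gene_id"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        genes_by_chrom[chrom] = ids
        n = len(ids)
        for i0 in range(0, n - W + 1, step):
            rows.append({
                "chrom": chrom, "start_idx": i0,
                "span_start": int(starts[i0:i0 + W].min()),
                "span_end": int(ends[i0:i0 + W].max()),
            })
    table = pd.DataFrame(rows, columns=["chrom", "start_idx", "span_start", "span_end"])
    return Windows(table, genes_by_chrom, W, step)


def window_poisson_test(k, W: int, genome_de_rate: float):
    """Inclusive upper-tail Poisson probability P(X >= k), lambda = W * rate."""
    if not (0.0 < genome_de_rate < 1.0):
        raise ValueError(f"genome_de_rate={genome_de_rate} must lie in (0, 1)")
    k = np.asarray(k)
    if (k < 0).any() or (k > W).any():
        raise ValueError("DE count k must satisfy 0 <= k <= W")
    lam = W * genome_de_rate
    return stats.poisson.sf(k - 1, lam)


def score_windows(windows: Windows, de_ids, genome_de_rate: float | None = None) -> Windows:
    """Fill k, lambda and p per window from the DE gene set.

    When ``genome_de_rate`` is None it is computed as (DE & expressed) /
    expressed over the genes that built the windows.
    """
    de = set(de_ids)
    n_expr = sum(len(v) for v in windows.genes_by_chrom.values())
    if genome_de_rate is None:
        n_de = sum(int(np.isin(v, list(de)).sum()) for v in windows.genes_by_chrom.values())
        genome_de_rate = n_de / n_expr if n_expr else 0.0
    tab = windows.table.copy()
    ks = np.empty(len(tab), dtype=int)
    for chrom, ids in windows.genes_by_chrom.items():
        is_de = np.isin(ids, list(de)).astype(int)
        csum = np.concatenate([[0], np.cumsum(is_de)])
        sel = tab["chrom"] == chrom
        i0 = tab.loc[sel, "start_idx"].to_numpy()
        ks[sel.to_numpy()] = csum[i0 + windows.W] - csum[i0]
    tab["k"] = ks
    tab["lam"] = windows.W * genome_de_rate
    tab["p"] = window_poisson_test(ks, windows.W, genome_de_rate) if len(tab) else []
    tab.attrs["genome_de_rate"] = genome_de_rate
    return Windows(tab, windows.genes_by_chrom, windows.W, windows.step)


def call_hotspots(windows: Windows, annotation: pd.DataFrame | None = None,
                  de_ids=(), fdr_threshold: float = 0.05) -> list:
    """BH over all windows genome-wide, then merge overlapping significant ones.

    Significant windows on the same chromosome sharing at least one gene
    are merged; hotspot fields come from the union of member genes.
    """
    tab = windows.table
    if "p" not in tab.columns:
        raise ValueError("windows must be scored before calling hotspots")
    if len(tab) == 0:
        return []
    q = bh_fdr(tab["p"].to_numpy())
    sig = tab[q < fdr_threshold]
    de = set(de_ids)
    ann_lookup = None
    if annotation is not None:
        ann_lookup = annotation.set_index("gene_id")
    hotspots = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        ids = windows.genes_by_chrom[chrom]
        # windows are [i0, i0+W-1] in expressed-gene index space; merge overlaps
        i0s = np.sort(sub["start_idx"].to_numpy())
        runs = []
        for i0 in i0s:
            if runs and i0 <= runs[-1][1]:            # shares >=1 gene
                runs[-1][1] = max(runs[-1][1], i0 + windows.W - 1)
            else:
                runs.append([i0, i0 + windows.W - 1])
        for lo, hi in runs:
            members = ids[lo:hi + 1]
            n_de = int(np.isin(members, list(de)).sum())
            if ann_lookup is not None:
                sub_ann = ann_lookup.loc[members]
                start, end = int(sub_ann["start"].min()), int(sub_ann["end"].max())
            else:
                within = windows.table[(windows.table["chrom"] == chrom)
                                       & windows.table["start_idx"].between(lo, hi)]
                start, end = int(within["span_start"].min()), int(within["span_end"].max())
            hotspots.append(Hotspot(chrom, start, end, tuple(members), len(members), n_de))
    rate = windows.table.attrs.get("genome_de_rate")
    if rate is not None:
        for h in hotspots:
            # upper-tail significance implies local enrichment above the rate
            assert h.pct_de > 100.0 * rate, (h, rate)
    return hotspots


def _modal_families(genes, de_ids, annotation) -> str:
    if annotation is None or "family" not in annotation.columns:
        return ""
    ann = annotation.set_index("gene_id")
    fams = [ann.loc[g, "family"] for g in genes if g in set(de_ids)]
    fams = [f for f in fams if f]
    if not fams:
        return ""
    counts = pd.Series(fams).value_counts()
    top = counts[counts == counts.max()]
    return ", ".join(sorted(top.index))


def summarize_hotspots(hotspots, genome_expressed: int, genome_de: int,
                       annotation: pd.DataFrame | None = None,
                       de_ids=()) -> pd.DataFrame:
    """Hotspot summary table with per-row stats plus totals and genome rows.

    Span is reported in Mb to 2 decimals, percent DE to 1 decimal
    (half-up), matching how such tables are conventionally printed.
    """
    rows = []
    for h in hotspots:
        rows.append({
            "chrom": h.chrom, "start": h.start, "end": h.end,
            "span_mb": round_half_up(h.span_mb, 2),
            "n_expressed": h.n_expressed, "n_de": h.n_de,
            "pct_de": percentage(h.n_de, h.n_expressed),
            "families": _modal_families(h.genes, de_ids, annotation),
        })
    total_span = sum(h.span_mb for h in hotspots)
    total_expr = sum(h.n_expressed for h in hotspots)
    total_de = sum(h.n_de for h in hotspots)
    rows.append({
        "chrom": "Hot Spot Totals", "start": None, "end": None,
        "span_mb": round_half_up(total_span, 2),
        "n_expressed": total_expr, "n_de": total_de,
        "pct_de": percentage(total_de, total_expr), "families": "",
    })
    rows.append({
        "chrom": "Whole Genome", "start": None, "end": None, "span_mb": None,
        "n_expressed": genome_expressed, "n_de": genome_de,
        "pct_de": percentage(genome_de, genome_expressed), "families": "",
    })
    return pd.DataFrame(rows)


def hotspots_from_counts(intervals: pd.DataFrame) -> list:
    """Build Hotspot records from a table of (chrom, start, end, n_expressed, n_de).

    Used for worked-example arithmetic on externally reported interval
    tables, where member gene identities are not available.
    """
    out = []
    for _, r in intervals.iterrows():
        out.append(Hotspot(str(r["chrom"]), int(r["start"]), int(r["end"]),
                           (), int(r["n_expressed"]), int(r["n_de"])))
    return out
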