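"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a four-strain, both-sex bulk RNA-seq design:

* negative-binomial counts (``Var = mu + alpha * mu**2``, per-gene alpha
  drawn log-normal) with uniform per-sample library-size factors;
* strain differential expression concentrated in planted genomic
  clusters — a high local DE rate inside 12 hotspot gene runs against a
  lower genome-wide rate (defaults 0.42 vs 0.128);
* X/Y homolog pairs with dosage compensation (female X mean equals male
  X plus male Y mean), zero female Y counts, and one female-only gene in
  the spirit of Xist;
* correlated and anti-correlated lncRNA/receptor blocks whose strain
  mean profiles are proportional or rank-reversed;
* genes with a sex effect confined to a single strain (Simpson's-paradox
  cases);
* pseudogene loci whose strain-specific SNVs or a single-base insertion
  restore a full-length open reading frame, together with a homolog at a
  controlled nucleotide/protein identity.

Every planted effect is recorded in :class:`SimTruth` so downstream
calls can be scored for sensitivity and false discovery.  Identical
parameters and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import stream_rng
from . import io as _io
from .io import Variant, VariantSet

SEXES = ("female", "male")
HOTSPOT_FAMILIES = ("GIMAP", "Vmn1r", "Vmn2r", "Clec", "Klr", "Olfr",
                    "Trim", "Cd200", "Fpr", "MHC", "Btnl", "Il")

__all__ = ["SimParams", "SimTruth", "SimData", "PseudogeneLocus",
           "simulate_counts", "simulate_xy_and_xist", "simulate_corr_blocks",
           "simulate_within_strain_sex", "simulate_pseudogene_locus",
           "simulate_dataset", "simulate_strain_profiles", "write_dataset"]


@dataclass
class SimParams:
    """Study-design parameters for the synthetic four-strain experiment."""

    strains: tuple = ("B6", "129", "SJL", "SWR")
    n_per_group: int = 4            # replicates per strain x sex
    n_genes: int = 10_000
    n_chromosomes: int = 5
    mean_log_mu: float = math.log(60.0)
    mean_log_sigma: float = 1.5
    dispersion_log_mu: float = math.log(0.08)
    dispersion_log_sigma: float = 0.5
    genome_de_rate: float = 0.128
    hotspot_local_de_rate: float = 0.42
    n_hotspots: int = 12
    #: expressed genes per planted cluster; the default follows the size
    #: distribution of reported VNO DE hotspots (25-122 genes, 575 total)
    hotspot_sizes: tuple = (25, 39, 46, 27, 62, 30, 67, 41, 32, 40, 44, 122)
    lfc_magnitude: float = 2.0
    libsize_low: float = 0.7
    libsize_high: float = 1.3
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (dispersion unidentifiable)")
        for name in ("genome_de_rate", "hotspot_local_de_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.hotspot_local_de_rate <= self.genome_de_rate:
            raise ValueError("hotspot_local_de_rate must exceed genome_de_rate")
        if sum(self.cluster_sizes()) > self.n_genes:
            raise ValueError("planted hotspots exceed the number of genes")

    def cluster_sizes(self) -> tuple:
        """Per-cluster gene counts, cycling the size pool to n_hotspots."""
        pool = self.hotspot_sizes
        return tuple(pool[i % len(pool)] for i in range(self.n_hotspots))


@dataclass
class SimTruth:
    """Everything planted by the generator, for scoring recovered calls."""

    de_lfc: dict = field(default_factory=dict)        # gene -> {strain: lfc}
    hotspot_intervals: list = field(default_factory=list)   # (chrom, start, end)
    hotspot_gene_sets: list = field(default_factory=list)
    xy_pairs: list = field(default_factory=list)
    female_only_gene: str | None = None
    corr_blocks: list = field(default_factory=list)
    within_strain_sex: dict = field(default_factory=dict)   # gene -> (strain, lfc)
    functional_pseudogenes: list = field(default_factory=list)  # (gene, strain)

    @property
    def de_genes(self) -> set:
        return set(self.de_lfc)

    def to_json(self) -> str:
        blob = asdict(self)
        blob["hotspot_intervals"] = [list(t) for t in self.hotspot_intervals]
        blob["hotspot_gene_sets"] = [list(t) for t in self.hotspot_gene_sets]
        blob["xy_pairs"] = [list(t) for t in self.xy_pairs]
        blob["within_strain_sex"] = {g: list(v) for g, v in self.within_strain_sex.items()}
        blob["functional_pseudogenes"] = [list(t) for t in self.functional_pseudogenes]
        return json.dumps(blob, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        blob = json.loads(text)
        return cls(
            de_lfc=blob["de_lfc"],
            hotspot_intervals=[tuple(t) for t in blob["hotspot_intervals"]],
            hotspot_gene_sets=[tuple(t) for t in blob["hotspot_gene_sets"]],
            xy_pairs=[tuple(t) for t in blob["xy_pairs"]],
            female_only_gene=blob["female_only_gene"],
            corr_blocks=blob["corr_blocks"],
            within_strain_sex={g: tuple(v) for g, v in blob["within_strain_sex"].items()},
            functional_pseudogenes=[tuple(t) for t in blob["functional_pseudogenes"]],
        )


@dataclass
class SimData:
    counts: pd.DataFrame
    meta: pd.DataFrame                  # sample_id, strain, sex, replicate, libsize
    annotation: pd.DataFrame
    truth: SimTruth
    params: SimParams
    pseudogene_loci: list = field(default_factory=list)


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, alpha) in the mean-dispersion form; alpha=0 falls back to Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = (alpha <= 0) & (mean > 0)
    nb = (alpha > 0) & (mean > 0)
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def _sample_table(params: SimParams) -> pd.DataFrame:
    rows = []
    for strain in params.strains:
        for sex in SEXES:
            for rep in range(1, params.n_per_group + 1):
                rows.append({
                    "sample_id": f"{strain}_{sex[0].upper()}{rep}",
                    "strain": strain, "sex": sex, "replicate": rep,
                })
    return pd.DataFrame(rows)


def simulate_counts(params: SimParams) -> SimData:
    """Core count matrix with planted strain DE concentrated in clusters.

    DE genes inside the planted hotspot runs arise at the local rate and
    elsewhere at a background rate chosen so the expected genome-wide DE
    fraction equals ``genome_de_rate``.  Each DE gene shifts one randomly
    chosen strain's mean by ``+-lfc_magnitude`` log2 units.  With
    ``lfc_magnitude == 0`` nothing is planted (null model).
    """
    rng = stream_rng(params.seed, 0)
    n, S = params.n_genes, len(params.strains)

    # genomic layout: genes in order along synthetic chromosomes
    per_chrom = np.full(params.n_chromosomes, n // params.n_chromosomes)
    per_chrom[: n % params.n_chromosomes] += 1
    chroms, starts, ends, lengths = [], [], [], []
    for ci, n_c in enumerate(per_chrom):
        gaps = rng.integers(5_000, 50_000, size=n_c)
        glen = rng.integers(500, 5_000, size=n_c)
        gstart = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(glen)[:-1]])
        chroms += [f"chr{ci + 1}"] * int(n_c)
        starts += list(gstart)
        ends += list(gstart + glen - 1)
        lengths += list(glen)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    annotation = pd.DataFrame({
        "gene_id": gene_ids, "chrom": chroms,
        "start": np.array(starts, dtype=int), "end": np.array(ends, dtype=int),
        "strand": ".", "biotype": "protein_coding", "family": None,
        "length_bp": np.array(lengths, dtype=int),
    })
    lnc = rng.random(n) < 0.05
    annotation.loc[lnc, "biotype"] = "lncRNA"

    # planted hotspot runs: contiguous genes, disjoint, spread over chromosomes
    chrom_offsets = np.concatenate([[0], np.cumsum(per_chrom)])
    hotspot_members, hotspot_intervals, hotspot_gene_sets = np.zeros(n, bool), [], []
    sizes = params.cluster_sizes()
    assignments = [i % params.n_chromosomes for i in range(params.n_hotspots)]
    for ci in range(params.n_chromosomes):
        mine = [h for h in range(params.n_hotspots) if assignments[h] == ci]
        if not mine:
            continue
        n_c = int(per_chrom[ci])
        block = n_c // len(mine)
        if block < max(sizes[h] for h in mine):
            raise ValueError("chromosome too short for its planted hotspots")
        for slot, _h in enumerate(mine):
            size = sizes[_h]
            lo = slot * block + int(rng.integers(0, block - size + 1))
            g0 = int(chrom_offsets[ci]) + lo
            members = np.arange(g0, g0 + size)
            hotspot_members[members] = True
            hotspot_intervals.append((f"chr{ci + 1}",
                                      int(annotation.loc[members[0], "start"]),
                                      int(annotation.loc[members[-1], "end"])))
            hotspot_gene_sets.append(tuple(gene_ids[g] for g in members))
            fam = HOTSPOT_FAMILIES[_h % len(HOTSPOT_FAMILIES)]
            annotation.loc[members, "family"] = fam

    # DE assignment: each cluster gets exactly round(local_rate * size) DE
    # members at random positions (so every planted cluster is recoverable
    # by construction); background genes are Bernoulli at a rate chosen to
    # make the expected genome-wide DE fraction equal genome_de_rate
    truth = SimTruth(hotspot_intervals=hotspot_intervals,
                     hotspot_gene_sets=hotspot_gene_sets)
    m_hot = int(hotspot_members.sum())
    bg_rate = (params.genome_de_rate * n - params.hotspot_local_de_rate * m_hot)
    bg_rate = max(bg_rate, 0.0) / max(n - m_hot, 1)
    is_de = (rng.random(n) < bg_rate) & ~hotspot_members
    hot_runs = np.flatnonzero(np.diff(np.concatenate([[0], hotspot_members.view(np.int8), [0]])))
    for lo, hi in zip(hot_runs[::2], hot_runs[1::2]):
        size = hi - lo
        n_de_c = int(round(params.hotspot_local_de_rate * size))
        picks = lo + rng.choice(size, size=n_de_c, replace=False)
        is_de[picks] = True
    if params.lfc_magnitude == 0:
        is_de[:] = False

    base_mean = rng.lognormal(params.mean_log_mu, params.mean_log_sigma, size=n)
    alpha = rng.lognormal(params.dispersion_log_mu, params.dispersion_log_sigma, size=n)
    means = np.tile(base_mean[:, None], (1, S))
    de_strain = rng.integers(0, S, size=n)
    de_sign = rng.choice([-1.0, 1.0], size=n)
    for gi in np.flatnonzero(is_de):
        lfc = float(de_sign[gi] * params.lfc_magnitude)
        means[gi, de_strain[gi]] *= 2.0 ** lfc
        truth.de_lfc[gene_ids[gi]] = {params.strains[de_strain[gi]]: lfc}

    meta = _sample_table(params)
    meta["libsize"] = rng.uniform(params.libsize_low, params.libsize_high, size=len(meta))
    strain_col = {s: i for i, s in enumerate(params.strains)}
    counts = np.empty((n, len(meta)), dtype=np.int64)
    for j, row in meta.iterrows():
        mu = means[:, strain_col[row["strain"]]] * row["libsize"]
        counts[:, j] = _nb_draws(rng, mu, alpha)
    counts = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                          columns=meta["sample_id"].to_numpy())
    return SimData(counts, meta, annotation, truth, params)


def _append_genes(data: SimData, rng, new_ids, chrom, mean_by_sample,
                  alpha=0.05, biotype="protein_coding", family=None,
                  exact_zero=None):
    """Append genes with per-sample NB means (genes x samples array)."""
    mu = np.asarray(mean_by_sample, dtype=float) * data.meta["libsize"].to_numpy()
    new_counts = _nb_draws(rng, mu, np.full(mu.shape, alpha))
    if exact_zero is not None:
        new_counts[exact_zero] = 0
    add = pd.DataFrame(new_counts, index=pd.Index(new_ids, name="gene_id"),
                       columns=data.counts.columns)
    data.counts = pd.concat([data.counts, add])
    tail = data.annotation["end"].max()
    ann_rows = []
    for k, gid in enumerate(new_ids):
        start = int(tail + 10_000 * (k + 1))
        ann_rows.append({"gene_id": gid, "chrom": chrom, "start": start,
                         "end": start + 1_499, "strand": ".", "biotype": biotype,
                         "family": family, "length_bp": 1_500})
    data.annotation = pd.concat([data.annotation, pd.DataFrame(ann_rows)],
                                ignore_index=True)


def simulate_xy_and_xist(data: SimData, n_pairs: int = 6) -> SimData:
    """Add dosage-compensated X/Y homolog pairs and a female-only gene.

    For each pair the female X mean equals the male X mean plus the male
    Y mean; Y genes have exactly zero counts in females, and the
    female-only gene has zero counts in males.
    """
    rng = stream_rng(data.params.seed, 1)
    meta = data.meta
    is_male = (meta["sex"] == "male").to_numpy()
    for i in range(n_pairs):
        x_f = rng.lognormal(math.log(150.0), 0.4)
        y_share = rng.uniform(0.25, 0.5)
        y_m = y_share * x_f
        x_m = x_f - y_m
        x_id, y_id = f"Xhom{i}", f"Yhom{i}"
        x_mu = np.where(is_male, x_m, x_f)[None, :]
        _append_genes(data, rng, [x_id], "chrX", x_mu)
        y_mu = np.where(is_male, y_m, 0.0)[None, :]
        _append_genes(data, rng, [y_id], "chrY", y_mu,
                      exact_zero=(np.zeros((1, len(meta)), bool) | ~is_male))
        data.truth.xy_pairs.append((x_id, y_id))
    xist_mu = np.where(is_male, 0.0, 400.0)[None, :]
    _append_genes(data, rng, ["XistLike"], "chrX", xist_mu, biotype="lncRNA",
                  exact_zero=(np.zeros((1, len(meta)), bool) | is_male))
    data.truth.female_only_gene = "XistLike"
    return data


def simulate_corr_blocks(data: SimData, block_size: int = 5) -> SimData:
    """Add a positively correlated lncRNA/receptor block and an antagonistic pair.

    Within the positive block every gene's strain means are proportional
    to one shared profile (pairwise Spearman of group means +1 before
    noise); the antagonistic pair uses the reversed profile (-1).
    """
    rng = stream_rng(data.params.seed, 2)
    strains = data.params.strains
    profile = 25.0 * 2.1 ** np.arange(len(strains))
    profile = rng.permutation(profile)
    strain_of = data.meta["strain"].map({s: i for i, s in enumerate(strains)}).to_numpy()
    per_sample = profile[strain_of]
    # monotone-decreasing transform of the profile: Spearman of the strain
    # means between the two blocks is exactly -1 before noise
    anti_profile = profile.max() + profile.min() - profile
    anti_per_sample = anti_profile[strain_of]

    pos_lnc = [f"LncPos{i}" for i in range(block_size)]
    pos_rcpt = [f"RcptPos{i}" for i in range(block_size)]
    for gid in pos_lnc:
        scale = rng.lognormal(0.0, 0.3)
        _append_genes(data, rng, [gid], "chrU", scale * per_sample[None, :],
                      biotype="lncRNA")
    for gid in pos_rcpt:
        scale = rng.lognormal(0.0, 0.3)
        _append_genes(data, rng, [gid], "chrU", scale * per_sample[None, :],
                      family="Vmn1r")
    _append_genes(data, rng, ["LncAnti"], "chrU", anti_per_sample[None, :],
                  biotype="lncRNA")
    _append_genes(data, rng, ["RcptAnti"], "chrU", per_sample[None, :],
                  family="Vmn2r")
    data.truth.corr_blocks = [
        {"lnc": pos_lnc, "receptors": pos_rcpt, "sign": 1,
         "profile": [float(x) for x in profile]},
        {"lnc": ["LncAnti"], "receptors": ["RcptAnti"], "sign": -1,
         "profile": [float(x) for x in anti_profile]},
    ]
    return data


def simulate_within_strain_sex(data: SimData, n_genes: int = 4,
                               lfc: float = 2.0) -> SimData:
    """Add genes whose sex effect exists in exactly one strain."""
    rng = stream_rng(data.params.seed, 3)
    strains = data.params.strains
    meta = data.meta
    for i in range(n_genes):
        strain = strains[i % len(strains)]
        base = rng.lognormal(math.log(120.0), 0.3)
        in_strain_male = ((meta["strain"] == strain) & (meta["sex"] == "male")).to_numpy()
        mu = np.where(in_strain_male, base * 2.0 ** lfc, base)[None, :]
        gid = f"SexWithin{i}"
        _append_genes(data, rng, [gid], "chrU", mu)
        data.truth.within_strain_sex[gid] = (strain, lfc)
    return data


# ---------------------------------------------------------------------------
# pseudogene loci
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_SENSE_CODONS = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
)
# codon boxes where any third base is synonymous (and never a stop)
_FOURFOLD_PREFIXES = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")

_CODON_AA = {}


def _aa(codon: str) -> str:
    if not _CODON_AA:
        from Bio.Seq import Seq
        for c in _SENSE_CODONS:
            _CODON_AA[c] = str(Seq(c).translate())
    return _CODON_AA[codon]


@dataclass
class PseudogeneLocus:
    gene_id: str
    reference: str              # pseudogene allele (premature stop / frameshift)
    restored: str               # allele with all variants applied
    variants: VariantSet
    homolog_id: str
    homolog: str
    strain: str
    expected: dict              # planted protein length, identities, flags


def _random_cds(rng, n_codons: int) -> list:
    """ATG + random sense codons + TAA, as a list of codons."""
    body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons)]
    return ["ATG"] + body + ["TAA"]


def _make_homolog(rng, codons, n_nonsyn: int, n_syn: int) -> str:
    """Copy of a CDS with exact counts of nonsynonymous and synonymous
    single-base codon changes (no indels), so identities are planted."""
    n_coding = len(codons) - 1                     # exclude terminal stop
    candidates = list(range(1, n_coding))          # keep ATG and stop intact
    rng.shuffle(candidates)
    hom = list(codons)
    nonsyn_done = syn_done = 0
    for ci in candidates:
        codon = hom[ci]
        if nonsyn_done < n_nonsyn:
            for first in rng.permutation(list(_BASES)):
                cand = str(first) + codon[1:]
                if cand != codon and cand in _SENSE_CODONS and _aa(cand) != _aa(codon):
                    hom[ci] = cand
                    nonsyn_done += 1
                    break
        elif syn_done < n_syn:
            if codon[:2] in _FOURFOLD_PREFIXES:
                third = rng.permutation([b for b in _BASES if b != codon[2]])[0]
                hom[ci] = codon[:2] + third
                syn_done += 1
        else:
            break
    if nonsyn_done < n_nonsyn or syn_done < n_syn:
        raise RuntimeError("could not place the requested substitutions")
    return "".join(hom)


def simulate_pseudogene_locus(seed: int, restore_mode: str = "snv_removes_stop",
                              strain: str = "SWR") -> PseudogeneLocus:
    """Reference pseudogene + variants that restore a full-length ORF.

    ``snv_removes_stop``: the reference carries two premature in-frame
    stops among ten strain-specific SNVs; applying them yields a 329-aa
    receptor whose designated homolog sits at a planted 91% nucleotide /
    ~84% protein identity.  ``insertion_restores_frame``: the reference
    lacks one base so the frame shifts 359 bp downstream of the start
    codon; a single C insertion restores a 318-aa ORF (planted 97% / ~95%
    identity to its homolog).
    """
    _aa("ATG")  # populate codon table
    if restore_mode == "snv_removes_stop":
        target_aa, n_nonsyn, n_syn = 329, 53, 36
    elif restore_mode == "insertion_restores_frame":
        target_aa, n_nonsyn, n_syn = 318, 16, 13
    else:
        raise ValueError(f"unknown restore_mode {restore_mode!r}")

    from .pseudogenes import find_orf  # local import to avoid a cycle

    for attempt in range(64):
        rng = stream_rng(seed, 10 + attempt)
        codons = _random_cds(rng, target_aa - 1)      # ATG + body + TAA
        full = "".join(codons)
        if restore_mode == "snv_removes_stop":
            coding = len(codons) - 1
            stop_sites = [int(rng.integers(40, 81)), int(rng.integers(180, 221))]
            variants = []
            for ci in stop_sites:
                codons[ci] = "TAC"                     # Tyr; TAC -> TAA is 1 nt
            full = "".join(codons)
            ref_list = list(full)
            for ci in stop_sites:
                pos = 3 * ci + 3                       # third base, 1-based
                ref_list[pos - 1] = "A"
                variants.append(Variant("locus", pos, "A", "C", "snv",
                                        frozenset([strain])))
            syn_sites = [ci for ci in range(1, coding)
                         if ci not in stop_sites and codons[ci][:2] in _FOURFOLD_PREFIXES]
            rng.shuffle(syn_sites)
            for ci in syn_sites[:8]:
                pos = 3 * ci + 3
                old = full[pos - 1]
                new = rng.permutation([b for b in _BASES if b != old])[0]
                ref_list[pos - 1] = new
                variants.append(Variant("locus", pos, new, old, "snv",
                                        frozenset([strain])))
            reference = "".join(ref_list)
        else:
            ci = 119                                   # codon covering bp 358-360
            prefix = _FOURFOLD_PREFIXES[int(rng.integers(0, len(_FOURFOLD_PREFIXES)))]
            codons[ci] = prefix + "C"                  # bp 360 is a C
            full = "".join(codons)
            reference = full[:359] + full[360:]        # drop the C at bp 360
            variants = [Variant("locus", 359, reference[358], reference[358] + "C",
                                "insertion", frozenset([strain]))]

        need = 0.95 * 3 * (target_aa + 1)
        ref_orf = find_orf(reference)
        full_orf = find_orf(full)
        if full_orf is None or len(full_orf) != len(full) or full_orf.start != 1:
            continue
        if ref_orf is not None and len(ref_orf) >= need:
            continue                                   # reference not pseudogenized
        hom_rng = stream_rng(seed, 100 + attempt)
        homolog = _make_homolog(hom_rng, list(codons), n_nonsyn, n_syn)
        if find_orf(homolog) is None or len(find_orf(homolog)) != len(homolog):
            continue
        gene_id = "PsSnv" if restore_mode == "snv_removes_stop" else "PsIns"
        n_nt = len(full)
        expected = {
            "protein_length": target_aa,
            "nt_identity": 100.0 * (n_nt - n_nonsyn - n_syn) / n_nt,
            "protein_identity": 100.0 * (target_aa - n_nonsyn) / target_aa,
            "stop_removed": restore_mode == "snv_removes_stop",
            "frame_restored": restore_mode == "insertion_restores_frame",
        }
        return PseudogeneLocus(gene_id, reference, full,
                               VariantSet(variants, (strain,)),
                               gene_id + "Homolog", homolog, strain, expected)
    raise RuntimeError("failed to construct a valid pseudogene locus")


# ---------------------------------------------------------------------------
# full bundles and helper generators
# ---------------------------------------------------------------------------

def simulate_dataset(params: SimParams, include_xy: bool = True,
                     include_corr: bool = True, include_sex_within: bool = True,
                     include_pseudogenes: bool = True) -> SimData:
    """Full synthetic study: counts plus every planted augmentation."""
    data = simulate_counts(params)
    if include_xy:
        simulate_xy_and_xist(data)
    if include_corr:
        simulate_corr_blocks(data)
    if include_sex_within:
        simulate_within_strain_sex(data)
    if include_pseudogenes:
        for mode in ("snv_removes_stop", "insertion_restores_frame"):
            locus = simulate_pseudogene_locus(params.seed, mode)
            data.pseudogene_loci.append(locus)
            data.truth.functional_pseudogenes.append((locus.gene_id, locus.strain))
    return data


def simulate_strain_profiles(seed: int, n_genes: int = 200,
                             strains: tuple = ("B6", "129", "SJL", "SWR")):
    """Gene x strain mean-expression profiles with a planted lineage.

    Emulates strain divergence on the tree (B6, (129, (SJL, SWR))): all
    strains share a gene's base expression; B6 carries the largest
    strain-specific deviation, 129 an intermediate one, and the two Swiss
    strains share a common deviation plus small private ones.  Returns
    ``(profiles, true_splits)`` where the splits are the leaf sets below
    the tree's internal nodes.
    """
    rng = stream_rng(seed, 4)
    base = rng.lognormal(math.log(100.0), 1.0, size=n_genes)
    e_b6 = rng.normal(0.0, 1.2, size=n_genes)
    e_129 = rng.normal(0.0, 0.6, size=n_genes)
    e_swiss = rng.normal(0.0, 0.6, size=n_genes)
    e_sjl = rng.normal(0.0, 0.25, size=n_genes)
    e_swr = rng.normal(0.0, 0.25, size=n_genes)
    cols = {
        "B6": base * 2.0 ** e_b6,
        "129": base * 2.0 ** e_129,
        "SJL": base * 2.0 ** (e_swiss + e_sjl),
        "SWR": base * 2.0 ** (e_swiss + e_swr),
    }
    profiles = pd.DataFrame({s: cols[s] for s in strains},
                            index=[f"g{i:04d}" for i in range(n_genes)])
    true_splits = [frozenset({"SJL", "SWR"}), frozenset({"129", "SJL", "SWR"})]
    return profiles, true_splits


def write_dataset(data: SimData, outdir: str | Path) -> Path:
    """Write counts.tsv, meta.tsv, genes.tsv, truth.json, loci.fasta, variants.vcf."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"params": asdict(data.params)}
    _io.write_counts(data.counts, out / "counts.tsv", params=prov, seed=data.params.seed)
    _io.write_sample_meta(data.meta[["sample_id", "strain", "sex", "replicate"]],
                          out / "meta.tsv", params=prov, seed=data.params.seed)
    _io.write_annotation(_io._finalize_annotation(data.annotation.copy()),
                         out / "genes.tsv", params=prov, seed=data.params.seed)
    (out / "truth.json").write_text(data.truth.to_json() + "\n")
    if data.pseudogene_loci:
        fasta = {}
        variants = []
        homolog_rows = []
        for locus in data.pseudogene_loci:
            fasta[locus.gene_id] = locus.reference
            fasta[locus.homolog_id] = locus.homolog
            for v in locus.variants.variants:
                variants.append(Variant(locus.gene_id, v.pos, v.ref, v.alt,
                                        v.kind, v.strains))
            homolog_rows.append({"gene_id": locus.gene_id,
                                 "homolog_id": locus.homolog_id})
        _io.write_fasta(fasta, out / "loci.fasta", seed=data.params.seed)
        _io.write_variants(VariantSet(variants, tuple(data.params.strains)),
                           out / "variants.vcf", seed=data.params.seed)
        pd.DataFrame(homolog_rows).to_csv(out / "homologs.tsv", sep="\t", index=False)
    return out
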