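"""Readers and writers for the on-disk formats the pipeline touches.

Conventions
-----------
* Counts: TSV, header ``gene_id<TAB>sample1...``, integer values.
* Sample metadata: TSV with columns ``sample_id, strain, sex, replicate``.
* Gene annotation: GFF3 (gene features with an ``ID`` attribute) or a TSV
  with explicit columns.  Coordinates are 1-based inclusive internally,
  matching GFF3/Ensembl usage; BED output is 0-based half-open.
* Variants: a VCF v4.2 subset restricted to SNVs and insertions, one
  sample column per strain carrying a presence/absence genotype.
* Sequences: FASTA.  Trees: Newick with support values as internal node
  labels.

Every writer emits a ``<path>.prov.json`` sidecar recording inputs,
parameters, seed and tool version so that any output can be traced back
to the run that produced it.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype", "family", "length_bp"]
META_COLUMNS = ["sample_id", "strain", "sex", "replicate"]
SEXES = {"male", "female"}


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def write_provenance(path: str | Path, *, inputs: Mapping | None = None,
                     params: Mapping | None = None, seed: int | None = None) -> Path:
    from . import __version__

    blob = {
        "tool": "vomeroseq",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": dict(inputs or {}),
        "params": dict(params or {}),
        "seed": seed,
    }
    out = Path(str(path) + ".prov.json")
    out.write_text(json.dumps(blob, indent=2, default=str) + "\n")
    return out


# ---------------------------------------------------------------------------
# counts and sample metadata
# ---------------------------------------------------------------------------

def validate_counts(counts: pd.DataFrame) -> None:
    """Raise ``ValueError`` unless ``counts`` is a valid gene x sample matrix."""
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in count matrix")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in count matrix")
    values = counts.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric values")
    if values.size:
        bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid count {values[g, s]!r} for gene {counts.index[g]!r} "
                f"in sample {counts.columns[s]!r}: counts must be non-negative integers"
            )


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count TSV into an integer DataFrame.

    Preserves input gene and sample ordering.  Ragged rows, duplicate
    identifiers and negative or non-integer values are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ValueError(f"duplicate sample id {dup!r} in count matrix header")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed count TSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    validate_counts(df)
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path, **provenance) -> None:
    validate_counts(counts)
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    write_provenance(path, **provenance)


def validate_sample_meta(meta: pd.DataFrame, counts: pd.DataFrame | None = None) -> None:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in metadata")
    bad_sex = set(meta["sex"]) - SEXES
    if bad_sex:
        raise ValueError(f"unknown sex label(s) {sorted(bad_sex)}; expected {sorted(SEXES)}")
    if (meta["replicate"].astype(int) < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    if counts is not None:
        meta_ids, count_ids = set(meta["sample_id"]), set(counts.columns)
        if meta_ids != count_ids:
            raise ValueError(
                f"metadata/count sample mismatch: only in metadata {sorted(meta_ids - count_ids)}, "
                f"only in counts {sorted(count_ids - meta_ids)}"
            )


def read_sample_meta(path: str | Path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str, "sex": str})
    validate_sample_meta(meta, counts)
    meta["replicate"] = meta["replicate"].astype(int)
    return meta.reset_index(drop=True)


def write_sample_meta(meta: pd.DataFrame, path: str | Path, **provenance) -> None:
    validate_sample_meta(meta)
    meta.to_csv(path, sep="\t", index=False)
    write_provenance(path, **provenance)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def validate_annotation(ann: pd.DataFrame) -> None:
    missing = [c for c in ("gene_id", "chrom", "start", "end") if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in annotation")
    if (ann["chrom"].astype(str).str.len() == 0).any():
        raise ValueError("annotation contains an empty chromosome name")
    bad = ann["start"] > ann["end"]
    if bad.any():
        row = ann[bad].iloc[0]
        raise ValueError(f"gene {row['gene_id']!r}: start {row['start']} > end {row['end']}")
    if "length_bp" in ann.columns and (ann["length_bp"] <= 0).any():
        row = ann[ann["length_bp"] <= 0].iloc[0]
        raise ValueError(f"gene {row['gene_id']!r}: non-positive length_bp")


def _finalize_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            ann[col] = None
    ann["start"] = ann["start"].astype(int)
    ann["end"] = ann["end"].astype(int)
    lengths = pd.to_numeric(ann["length_bp"], errors="coerce")
    ann["length_bp"] = lengths.fillna(ann["end"] - ann["start"] + 1).astype(int)
    ann["strand"] = ann["strand"].fillna(".")
    ann["family"] = ann["family"].where(pd.notna(ann["family"]), None)
    validate_annotation(ann)
    return (
        ann[ANNOTATION_COLUMNS]
        .sort_values(["chrom", "start", "end", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def _read_annotation_gff3(path: str | Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        biotype = (attrs.get("biotype") or attrs.get("gene_biotype") or ["protein_coding"])[0]
        family = (attrs.get("family") or [None])[0]
        length = attrs.get("length_bp")
        rows.append({
            "gene_id": (attrs.get("ID") or [feat.id])[0],
            "chrom": feat.seqid,
            "start": feat.start,
            "end": feat.end,
            "strand": feat.strand or ".",
            "biotype": biotype,
            "family": family,
            "length_bp": int(length[0]) if length else None,
        })
    if not rows:
        raise ValueError(f"no gene features found in GFF3 {path}")
    return pd.DataFrame(rows)


def read_annotation(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read gene annotation, returning records sorted by (chrom, start).

    Coordinates are 1-based inclusive regardless of dialect.
    """
    if dialect == "gff3":
        ann = _read_annotation_gff3(path)
    elif dialect == "tsv":
        ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}; expected 'gff3' or 'tsv'")
    return _finalize_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path, **provenance) -> None:
    validate_annotation(ann)
    ann.to_csv(path, sep="\t", index=False)
    write_provenance(path, **provenance)


def check_annotation_covers(counts: pd.DataFrame, ann: pd.DataFrame) -> None:
    """Reject count genes absent from the annotation rather than guessing."""
    missing = set(counts.index) - set(ann["gene_id"])
    if missing:
        some = sorted(missing)[:5]
        raise ValueError(
            f"{len(missing)} gene(s) in the count matrix are absent from the "
            f"annotation (e.g. {some}); annotate or drop them explicitly"
        )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Variant:
    """A single SNV or insertion, keyed to a reference sequence position."""

    chrom: str
    pos: int            # 1-based position on the reference sequence
    ref: str
    alt: str
    kind: str = field(compare=False)  # "snv" | "insertion"
    strains: frozenset = field(compare=False, default_factory=frozenset)

    @property
    def inserted(self) -> str:
        return self.alt[len(self.ref):] if self.kind == "insertion" else ""


@dataclass
class VariantSet:
    """Validated collection of SNVs/insertions with their carrier strains."""

    variants: list
    strains: tuple = ()

    def __len__(self) -> int:
        return len(self.variants)

    def for_strain(self, strain: str) -> list:
        return [v for v in self.variants if strain in v.strains]

    def for_chrom(self, chrom: str) -> list:
        return [v for v in self.variants if v.chrom == chrom]


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    if len(alt) > len(ref) and alt.startswith(ref) and len(ref) == 1:
        return "insertion"
    raise ValueError(
        f"unsupported variant class REF={ref!r} ALT={alt!r}: only SNVs and "
        "simple insertions are handled (no deletions, no complex alleles)"
    )


def read_variants(path: str | Path) -> VariantSet:
    """Read the supported VCF v4.2 subset (SNVs and insertions).

    Each VCF sample column is a strain; a non-reference genotype marks the
    strain as carrying the variant.  Deletions or multi-allelic records
    raise an 'unsupported variant class' error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = tuple(vcf.samples)
    variants = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"unsupported variant class at {rec.CHROM}:{rec.POS}: "
                "multi-allelic records are not handled"
            )
        ref, alt = rec.REF, rec.ALT[0]
        kind = classify_variant(ref, alt)
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        carriers = frozenset(s for s, g in zip(strains, rec.gt_types) if g in (1, 3))
        variants.append(Variant(rec.CHROM, rec.POS, ref, alt, kind, carriers))
    return VariantSet(variants, strains)


def write_variants(vs: VariantSet, path: str | Path, **provenance) -> None:
    strains = vs.strains or tuple(sorted({s for v in vs.variants for s in v.strains}))
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted({v.chrom for v in vs.variants}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(strains))
    for v in sorted(vs.variants, key=lambda v: (v.chrom, v.pos)):
        gts = "\t".join("1/1" if s in v.strains else "0/0" for s in strains)
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")
    write_provenance(path, **provenance)


# ---------------------------------------------------------------------------
# FASTA, Newick, BED
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict:
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70,
                **provenance) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    write_provenance(path, **provenance)


def write_newick(newick: str, path: str | Path, **provenance) -> None:
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")
    write_provenance(path, **provenance)


def intervals_to_bed(intervals: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive intervals -> 0-based half-open BED records."""
    bed = intervals[["chrom", "start", "end"]].copy()
    if (bed["start"] < 1).any():
        raise ValueError("1-based interval start below 1")
    bed["start"] = bed["start"] - 1
    return bed


def bed_to_intervals(bed: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED records -> 1-based inclusive intervals."""
    iv = bed[["chrom", "start", "end"]].copy()
    iv["start"] = iv["start"] + 1
    return iv


def write_bed(intervals: pd.DataFrame, path: str | Path, names: Sequence[str] | None = None,
              **provenance) -> None:
    bed = intervals_to_bed(intervals)
    if names is not None:
        bed["name"] = list(names)
    bed.to_csv(path, sep="\t", index=False, header=False)
    write_provenance(path, **provenance)
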