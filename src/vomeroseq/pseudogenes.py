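"""SNV/insertion-aware pseudogene functionalization.

Applies a strain's variants to a reference gene sequence, reconstructs
the longest open reading frame, translates it, and decides whether the
strain's allele is a functionalized receptor: a pseudogene whose variants
restore a full-length ORF (premature stop removed by an SNV, or reading
frame restored by an insertion).  Percent identity to a user-declared
homolog is computed by global alignment with fixed, documented scoring so
the reported percentages are bit-reproducible.

Sequences are supplied sense-strand per gene, so ORF search is restricted
to the three forward frames.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import Variant, VariantSet

STOP_CODONS = {"TAA", "TAG", "TGA"}

__all__ = ["ORF", "ORFReport", "apply_variants", "find_orf", "translate",
           "percent_identity", "call_functionalization"]


@dataclass(frozen=True)
class ORF:
    """1-based inclusive coordinates of an ORF, terminal stop included."""

    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ORFReport:
    strain: str
    orf: ORF | None
    protein: str
    protein_length: int                  # aa, excluding the stop
    stop_removed: bool
    frame_restored: bool
    protein_identity: float | None       # % identity to homolog protein
    nt_identity: float | None            # % identity to homolog ORF nucleotides
    functional: bool


def apply_variants(refseq: str, variants: VariantSet | list, strain: str) -> str:
    """Apply a strain's SNVs and insertions to a reference sequence.

    Positions refer to the *original* reference (1-based); edits are
    applied right-to-left so earlier insertions cannot shift later
    coordinates.  REF alleles are verified against the sequence.
    """
    if isinstance(variants, VariantSet):
        variants = variants.variants
    mine = sorted((v for v in variants if strain in v.strains),
                  key=lambda v: v.pos, reverse=True)
    seen = set()
    for v in mine:
        if v.pos in seen:
            raise ValueError(f"multiple variants at position {v.pos}")
        seen.add(v.pos)
    seq = refseq
    for v in mine:
        if not 1 <= v.pos <= len(refseq):
            raise ValueError(f"variant position {v.pos} outside sequence of length {len(refseq)}")
        if refseq[v.pos - 1:v.pos - 1 + len(v.ref)] != v.ref:
            raise ValueError(
                f"REF mismatch at position {v.pos}: expected {v.ref!r}, "
                f"found {refseq[v.pos - 1:v.pos - 1 + len(v.ref)]!r}"
            )
        if v.kind == "snv":
            seq = seq[:v.pos - 1] + v.alt + seq[v.pos:]
        elif v.kind == "insertion":
            seq = seq[:v.pos] + v.inserted + seq[v.pos:]
        else:
            raise ValueError(f"unsupported variant kind {v.kind!r}")
    return seq


def find_orf(seq: str) -> ORF | None:
    """Longest ATG-initiated ORF ending at the first in-frame stop.

    All three forward frames are searched; ties break to the earliest
    start.  Returns None when no ATG-to-stop ORF exists.
    """
    seq = seq.upper()
    best: ORF | None = None
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i:i + 3] == "ATG":
                j = i
                while j + 3 <= len(seq):
                    if seq[j:j + 3] in STOP_CODONS:
                        cand = ORF(i + 1, j + 3)
                        if best is None or len(cand) > len(best) or \
                           (len(cand) == len(best) and cand.start < best.start):
                            best = cand
                        break
                    j += 3
                # any later ATG in this frame before the same stop yields a
                # shorter ORF, so jump past the stop (or end) we just hit
                i = j + 3 if j + 3 <= len(seq) else len(seq)
            else:
                i += 3
    return best


def translate(orf_nt: str) -> str:
    """Translate an ORF (standard code), excluding the terminal stop."""
    if len(orf_nt) % 3 != 0:
        raise ValueError(f"ORF length {len(orf_nt)} is not divisible by 3")
    protein = str(Seq(orf_nt).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError("internal stop codon in ORF")
    return protein


def _aligner(alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "nt":
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
    elif alphabet == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}; expected 'nt' or 'aa'")
    return aligner


def percent_identity(a: str, b: str, alphabet: str = "nt") -> float:
    """Global-alignment percent identity: 100 * matches / alignment columns."""
    if not a or not b:
        raise ValueError("percent identity of an empty sequence is undefined")
    aln = _aligner(alphabet).align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def call_functionalization(refseq: str, variants: VariantSet | list, strain: str,
                           homolog: str, length_fraction: float = 0.95) -> ORFReport:
    """Decide whether a strain's variants functionalize a pseudogene.

    Functional = the edited sequence's longest ORF covers at least
    ``length_fraction`` of the homolog's ORF length while the reference's
    longest ORF does not.  ``stop_removed`` / ``frame_restored`` diagnose
    how the ORF was rescued (an in-frame premature stop erased by an SNV,
    or a frameshift repaired by an insertion).
    """
    if isinstance(variants, VariantSet):
        variants = variants.variants
    edited = apply_variants(refseq, variants, strain)
    applied = [v for v in variants if strain in v.strains]
    ref_orf = find_orf(refseq)
    ed_orf = find_orf(edited)
    hom_orf = find_orf(homolog)
    if hom_orf is None:
        raise ValueError("homolog sequence has no ATG-initiated ORF")
    hom_nt = homolog[hom_orf.start - 1:hom_orf.end]
    hom_protein = translate(hom_nt)

    need = length_fraction * len(hom_orf)
    ref_full = ref_orf is not None and len(ref_orf) >= need
    ed_full = ed_orf is not None and len(ed_orf) >= need
    functional = ed_full and not ref_full

    protein, protein_len, prot_id, nt_id = "", 0, None, None
    if ed_orf is not None:
        ed_nt = edited[ed_orf.start - 1:ed_orf.end]
        protein = translate(ed_nt)
        protein_len = len(protein)
        prot_id = percent_identity(protein, hom_protein, "aa")
        nt_id = percent_identity(ed_nt, hom_nt, "nt")

    has_insertion = any(v.kind == "insertion" for v in applied)
    frame_restored = functional and has_insertion
    stop_removed = False
    if functional and ed_orf is not None and any(v.kind == "snv" for v in applied):
        # project the edited ORF start back to reference coordinates by
        # subtracting inserted bases upstream, then look for an in-frame
        # premature stop in the unedited reference over the ORF span
        shift = sum(len(v.inserted) for v in applied
                    if v.kind == "insertion" and v.pos < ed_orf.start)
        ref_start = ed_orf.start - shift
        frame_seq = refseq[ref_start - 1:]
        codons = [frame_seq[i:i + 3] for i in range(0, len(frame_seq) - 2, 3)]
        first_stop = next((ci for ci, c in enumerate(codons) if c in STOP_CODONS), None)
        stop_removed = first_stop is not None and 3 * (first_stop + 1) < len(ed_orf)

    return ORFReport(
        strain=strain, orf=ed_orf, protein=protein, protein_length=protein_len,
        stop_removed=stop_removed, frame_restored=frame_restored,
        protein_identity=prot_id, nt_identity=nt_id, functional=functional,
    )
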