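"""Published reference tallies from a four-strain mouse VNO expression survey.

These serve as worked-example *inputs*: the bundled hotspot table carries
only the reported interval coordinates and expressed/DE gene counts; all
derived columns (span in Mb, percent DE, totals, the genome-wide DE rate)
are recomputed by :func:`vomeroseq.hotspots.summarize_hotspots` and the
ratio helpers, which lets the summary arithmetic be validated end to end
against what the survey printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: genes detected as expressed by any sample, and how many were DE between
#: strains (fold change > 2, FDR < 0.05 in at least one pairwise contrast)
GENOME_EXPRESSED = 44957
GENOME_DE = 5745

#: DE genes annotated only as gene models (Gm) or Riken (Rik) transcripts
GM_RIK_DE = 1644

#: chemosensory receptor families: (genes lacking expression in >=1 strain,
#: DE genes in the family)
FAMILY_LACKING = {
    "V1r": (14, 114),
    "V2r": (9, 111),
    "Olfr": (92, 141),
}


def load_reference_hotspots() -> pd.DataFrame:
    """The 12 reported DE hotspot intervals (mm10 coordinates, 1-based)."""
    with resources.files("vomeroseq.data").joinpath("vno_hotspots_reference.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return df
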