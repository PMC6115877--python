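"""Gene-level annotation of introgressed windows from GFF3 gene models.

A gene is reported when it overlaps at least one introgressed window by at
least one base (half-open interval intersection); a stricter containment
mode (gene fully inside the window) is available behind a flag.  Functional
annotation is out of scope — the report carries GFF attribute text so
downstream joins against external databases stay possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = ["GeneModel", "load_gff", "genes_in_regions", "AnnotationError"]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene feature in 0-based half-open coordinates."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."
    attributes: str = ""

    def __post_init__(self):
        if not self.scaffold:
            raise AnnotationError("gene with empty scaffold")
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start must be < end ({self.start}, {self.end})"
            )


def load_gff(path, feature_type: str = "gene") -> list[GeneModel]:
    """Parse GFF3 ``feature_type`` records into GeneModels.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open;
    genes are returned sorted by (scaffold, start).  The gene identifier is
    the ID attribute, falling back to Name, else a positional placeholder.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        if isinstance(exc, gffutils.exceptions.EmptyInputError) or \
                "No lines parsed" in str(exc):
            logger.warning("%s: no %r features found", path, feature_type)
            return []
        raise AnnotationError(f"{path}: failed to parse GFF3: {exc}") from exc

    genes = []
    for i, feat in enumerate(db.features_of_type(feature_type)):
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("Name")
                   or [f"{feature_type}_{i}"])[0]
        attrs = ";".join(
            f"{k}={','.join(v)}" for k, v in sorted(feat.attributes.items())
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand or ".",
                attributes=attrs,
            )
        )
    if not genes:
        logger.warning("%s: no %r features found", path, feature_type)
    genes.sort(key=lambda g: (g.scaffold, g.start))
    return genes


def _region_interval(region) -> tuple[str, int, int]:
    """Accept IntrogressedRegion, WindowStats or a (scaffold, start, end)."""
    if hasattr(region, "interval"):
        return region.interval
    scaffold, start, end = region[0], int(region[1]), int(region[2])
    return scaffold, start, end


def genes_in_regions(
    genes: Sequence[GeneModel],
    regions: Sequence,
    containment: bool = False,
) -> pd.DataFrame:
    """Report every (gene, region) pair with >= 1 bp overlap.

    Columns: gene_id, scaffold, gene_start, gene_end, strand, region_start,
    region_end, overlap_bp, attributes.  With ``containment`` the gene must
    lie entirely inside the region.  Rows are unique per (gene, region) and
    sorted by (scaffold, gene_start, region_start).
    """
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        scaffold, start, end = _region_interval(region)
        trees.setdefault(scaffold, IntervalTree()).addi(start, end)

    rows = []
    seen = set()
    for g in genes:
        tree = trees.get(g.scaffold)
        if tree is None:
            continue
        for iv in tree.overlap(g.start, g.end):
            if containment and not (iv.begin <= g.start and g.end <= iv.end):
                continue
            key = (g.gene_id, g.scaffold, iv.begin, iv.end)
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "scaffold": g.scaffold,
                    "gene_start": g.start,
                    "gene_end": g.end,
                    "strand": g.strand,
                    "region_start": iv.begin,
                    "region_end": iv.end,
                    "overlap_bp": min(g.end, iv.end) - max(g.start, iv.begin),
                    "attributes": g.attributes,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "scaffold", "gene_start", "gene_end", "strand",
            "region_start", "region_end", "overlap_bp", "attributes",
        ],
    )
    return df.sort_values(
        ["scaffold", "gene_start", "region_start"], kind="mergesort"
    ).reset_index(drop=True)
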