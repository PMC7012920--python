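"""Candidate-gene extraction: interval-to-gene overlap plus pathway
annotation against a packaged anthocyanin-biosynthesis gene table.

The packaged table carries the *Brassica rapa* anthocyanin regulators
relevant to the purple-leaf trait (*BrMYBL2.1*, a negative regulator, and
the *BrEGL3* homeologs, positive regulators) and is user-extensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .depthscan import DipCall
from .qtlseq import CandidateInterval

__all__ = [
    "GeneRecord",
    "read_gff3_genes",
    "load_pathway_table",
    "packaged_pathway_table",
    "genes_in_interval",
    "report_candidates",
]

PATHWAY_ROLES = ("positive_regulator", "negative_regulator", "structural", "none")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    pathway_role: str = "none"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.pathway_role not in PATHWAY_ROLES:
            raise ValueError(f"unknown pathway role {self.pathway_role!r}")


def read_gff3_genes(path: str, feature_type: str = "gene") -> list[GeneRecord]:
    """Load gene records from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [None])[0]
        genes.append(
            GeneRecord(gene_id, feat.seqid, feat.start, feat.end, feat.strand, name)
        )
    return genes


def load_pathway_table(path) -> pd.DataFrame:
    """Read a pathway annotation TSV with a '#'-prefixed header line and
    columns gene_id, name, chrom, start, end, role."""
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def packaged_pathway_table() -> pd.DataFrame:
    """The packaged anthocyanin-pathway gene table."""
    with resources.files("poolmap.data").joinpath("anthocyanin_genes.tsv").open() as fh:
        return load_pathway_table(fh)


def annotate_roles(
    genes: Iterable[GeneRecord], pathway: pd.DataFrame | None
) -> list[GeneRecord]:
    """Copy pathway roles (and display names) onto gene records by id."""
    if pathway is None:
        return list(genes)
    roles = dict(zip(pathway["gene_id"], pathway["role"]))
    names = dict(zip(pathway["gene_id"], pathway.get("name", pathway["gene_id"])))
    out = []
    for g in genes:
        if g.gene_id in roles:
            out.append(
                GeneRecord(
                    g.gene_id, g.chromosome, g.start, g.end, g.strand,
                    names.get(g.gene_id, g.name), roles[g.gene_id],
                )
            )
        else:
            out.append(g)
    return out


def genes_in_interval(
    interval: CandidateInterval,
    annotation: Sequence[GeneRecord],
    min_overlap: int = 1,
    pathway: pd.DataFrame | None = None,
) -> list[GeneRecord]:
    """Genes overlapping the refined interval by at least ``min_overlap`` bp,
    sorted by start position."""
    annotation = annotate_roles(annotation, pathway)
    on_chrom = [g for g in annotation if g.chromosome == interval.chromosome]
    if not on_chrom and annotation:
        warnings.warn(
            f"chromosome {interval.chromosome!r} absent from annotation"
        )
        return []
    lo, hi = interval.refined_start, interval.refined_end
    hits = [
        g
        for g in on_chrom
        if min(g.end, hi) - max(g.start, lo) + 1 >= min_overlap
    ]
    return sorted(hits, key=lambda g: g.start)


def report_candidates(
    intervals: Sequence[CandidateInterval],
    dipcalls: Sequence[DipCall],
    annotation: Sequence[GeneRecord],
    pathway: pd.DataFrame | None = None,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Ranked candidate table joining intervals, genes, pathway roles, and
    depth dips contained in gene bodies.

    Genes with both a pathway role and a contained dip rank first, then
    pathway-role-only, then dip-only, then the rest; within a rank genes
    are ordered by genomic position.
    """
    rows = []
    for interval in intervals:
        for gene in genes_in_interval(interval, annotation, min_overlap, pathway):
            dips = [
                d
                for d in dipcalls
                if d.chromosome == gene.chromosome
                and d.start >= gene.start
                and d.end <= gene.end
            ]
            has_role = gene.pathway_role != "none"
            rank = (
                0 if (has_role and dips) else 1 if has_role else 2 if dips else 3
            )
            rows.append(
                {
                    "interval": f"{interval.chromosome}:{interval.refined_start}-{interval.refined_end}",
                    "gene_id": gene.gene_id,
                    "name": gene.name or gene.gene_id,
                    "chrom": gene.chromosome,
                    "start": gene.start,
                    "end": gene.end,
                    "pathway_role": gene.pathway_role,
                    "n_dips": len(dips),
                    "dip_spans": ";".join(f"{d.start}-{d.end}" for d in dips),
                    "rank": rank,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "interval", "gene_id", "name", "chrom", "start", "end",
            "pathway_role", "n_dips", "dip_spans", "rank",
        ],
    )
    if len(df):
        df = df.sort_values(["rank", "chrom", "start"], kind="stable").reset_index(drop=True)
    return df
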