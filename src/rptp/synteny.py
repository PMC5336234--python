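"""Conserved-synteny comparison of gene neighborhoods around anchor loci.

Given the ordered genes around an anchor locus in genome A and a table of
gene locations in genome B, each neighbor is classified as *conserved*
(present in B on the same chromosome/scaffold as B's anchor), *elsewhere*
(present in B but on another scaffold) or *absent* (no ortholog in B).
Orthology is by name, via an optional user-supplied mapping table; sequence
based orthology inference is out of scope.

The packaged fixture encodes the vertebrate PTPRB neighborhood (CCT2,
LRCC10, BEST3, MYRFL, CNOT2, KCNMB4, PTPRR, LGR5) against the Ciona
intestinalis gene set, where only BEST3 and CNOT2 remain linked to the
Ciona_1 locus and LRCC10, MYRFL and KCNMB4 are missing from the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import ValidationError


@dataclass
class Neighborhood:
    """Ordered gene neighborhood around an anchor locus in one genome."""

    genome: str
    anchor: str
    neighbors: list[tuple[str, str]]  # (gene name, location string)

    def __post_init__(self) -> None:
        names = [g for g, _ in self.neighbors]
        if self.anchor in names:
            raise ValidationError("anchor must not be listed among neighbors")
        if len(set(names)) != len(names):
            raise ValidationError("neighbor gene names must be unique")


@dataclass
class SyntenyReport:
    conserved: list[str]
    absent: list[str]
    elsewhere: list[str]

    def as_frame(self) -> pd.DataFrame:
        rows = ([(g, "conserved") for g in self.conserved]
                + [(g, "elsewhere") for g in self.elsewhere]
                + [(g, "absent") for g in self.absent])
        return pd.DataFrame(rows, columns=["gene", "status"])


def compare_neighborhoods(a: Neighborhood,
                          b_genes: dict[str, str],
                          b_anchor: str,
                          orthology: dict[str, str] | None = None
                          ) -> SyntenyReport:
    """Classify each neighbor of ``a`` against genome B.

    ``b_genes`` maps gene name -> chromosome/scaffold in B; ``b_anchor`` is
    the name of B's anchor locus, which must be present in ``b_genes``.
    ``orthology`` optionally renames A-side genes to their B-side names.
    The three output lists partition the neighbors exactly.
    """
    if not a.neighbors:
        raise ValidationError("empty neighborhood")
    if b_anchor not in b_genes:
        raise ValidationError(f"unknown anchor {b_anchor!r} in genome B")
    anchor_scaffold = b_genes[b_anchor]
    orthology = orthology or {}
    conserved, absent, elsewhere = [], [], []
    for gene, _loc in a.neighbors:
        b_name = orthology.get(gene, gene)
        if b_name not in b_genes:
            absent.append(gene)
        elif b_genes[b_name] == anchor_scaffold:
            conserved.append(gene)
        else:
            elsewhere.append(gene)
    return SyntenyReport(conserved=conserved, absent=absent,
                         elsewhere=elsewhere)


# ------------------------------------------------------ packaged fixture

def load_neighborhood_tsv(path_or_text: str, genome: str) -> Neighborhood:
    """Neighborhood TSV: columns genome, anchor, gene, chromosome, start."""
    df = pd.read_csv(path_or_text, sep="\t")
    df = df[df["genome"] == genome]
    if df.empty:
        raise ValidationError(f"no rows for genome {genome!r}")
    anchors = df["anchor"].unique()
    if len(anchors) != 1:
        raise ValidationError("neighborhood table must have a single anchor")
    df = df.sort_values("start")
    return Neighborhood(
        genome=genome, anchor=str(anchors[0]),
        neighbors=[(str(r.gene), f"{r.chromosome}:{r.start}")
                   for r in df.itertuples()])


def ptprb_vs_ciona() -> tuple[Neighborhood, dict[str, str], str]:
    """The packaged worked example: vertebrate PTPRB neighbors against the
    Ciona intestinalis gene complement around the Ciona_1 locus."""
    data = resources.files("rptp.data")
    with resources.as_file(data / "ptprb_neighborhood.tsv") as p:
        hood = load_neighborhood_tsv(str(p), genome="human")
    ciona = pd.read_csv(str(data / "ciona_gene_locations.tsv"), sep="\t")
    b_genes = dict(zip(ciona["gene"], ciona["chromosome"].astype(str)))
    return hood, b_genes, "Ciona_1"
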