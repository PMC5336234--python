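"""Core domain types: protein records, gene models, domain intervals, matrices.

Coordinate conventions
----------------------
All coordinates are 0-based half-open internally.  GFF-style 1-based closed
coordinates appear only at file boundaries and are converted on read/write:
``(s, e)_gff == (s - 1, e)_internal``.

Gene models are stored in transcript (5'→3') orientation regardless of
genomic strand; minus-strand models are flipped on read so downstream
intron-phase arithmetic never needs to know the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeneModelError, ValidationError

#: The 20 standard amino acids plus X for ambiguity.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """A single curated protein sequence.

    Parameters
    ----------
    id:
        Unique identifier within a collection (e.g. ``Hs_PTPRB``).
    sequence:
        Upper-case amino-acid string over the 20 standard letters plus X.
        Gap characters are not allowed; records hold raw sequences, never
        alignment rows.
    species:
        Free-text species name.
    source:
        Free-text provenance (accession number, simulation tag, ...).
    """

    id: str
    sequence: str
    species: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: illegal characters {sorted(bad)!r} "
                "(sequences must be uppercase amino acids, no gaps)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """Exon structure of a protein-coding gene.

    ``exons`` are genomic (start, end) pairs, 0-based half-open, listed in
    transcript order (5'→3').  For minus-strand genes this means genomic
    coordinates decrease along the list.  ``cds_lengths`` are the per-exon
    coding lengths in nucleotides; by default each exon is fully coding.
    """

    protein_id: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    cds_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(
                f"gene {self.protein_id!r}: strand must be '+' or '-'"
            )
        if not self.exons:
            raise GeneModelError(f"gene {self.protein_id!r}: no exons")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise GeneModelError(
                    f"gene {self.protein_id!r}: bad exon ({s}, {e})"
                )
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise GeneModelError(
                f"gene {self.protein_id!r}: exons not in transcript order"
            )
        spans = sorted(self.exons)
        for (_, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise GeneModelError(
                    f"gene {self.protein_id!r}: overlapping exons"
                )
        if not self.cds_lengths:
            self.cds_lengths = [e - s for s, e in self.exons]
        if len(self.cds_lengths) != len(self.exons):
            raise GeneModelError(
                f"gene {self.protein_id!r}: cds_lengths/exons length mismatch"
            )

    @property
    def cds_length(self) -> int:
        return sum(self.cds_lengths)

    def validate_frame(self, protein_length: int | None = None,
                       stop_included: bool = True) -> None:
        """Check the reading frame and, optionally, the protein length.

        With ``stop_included`` (GenBank CDS dialect) the CDS covers the stop
        codon and the protein has ``cds/3 - 1`` residues; without it (CDS
        fragments) the protein has ``cds/3`` residues.
        """
        total = self.cds_length
        if total % 3 != 0:
            raise GeneModelError(
                f"gene {self.protein_id!r}: CDS length {total} not divisible by 3"
            )
        if protein_length is not None:
            expected = total // 3 - 1 if stop_included else total // 3
            if expected != protein_length:
                raise GeneModelError(
                    f"gene {self.protein_id!r}: CDS implies {expected} residues, "
                    f"protein has {protein_length}"
                )


@dataclass(frozen=True)
class DomainAnnotation:
    """A typed interval on a protein, 0-based half-open.

    FN3 repeats carry an ``ordinal``; numbering starts at 1 for the repeat
    closest to the transmembrane segment and increases toward the N terminus.
    """

    protein_id: str
    kind: str  # FN3 | PTP | TM | SP
    start: int
    end: int
    ordinal: int | None = None

    KINDS = ("FN3", "PTP", "TM", "SP")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(
                f"domain on {self.protein_id!r}: unknown kind {self.kind!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"domain on {self.protein_id!r}: bad interval "
                f"[{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def check_domains(domains: Sequence[DomainAnnotation],
                  proteins: dict[str, ProteinRecord] | None = None) -> None:
    """Validate a domain table: bounds within proteins, unique FN3 ordinals."""
    seen: dict[tuple[str, int], DomainAnnotation] = {}
    for d in domains:
        if proteins is not None:
            if d.protein_id not in proteins:
                raise ValidationError(f"domain refers to unknown protein {d.protein_id!r}")
            if d.end > len(proteins[d.protein_id]):
                raise ValidationError(
                    f"domain on {d.protein_id!r} ends at {d.end}, beyond protein length"
                )
        if d.kind == "FN3":
            if d.ordinal is None:
                raise ValidationError(f"FN3 domain on {d.protein_id!r} lacks an ordinal")
            key = (d.protein_id, d.ordinal)
            if key in seen:
                raise ValidationError(
                    f"duplicate FN3 ordinal {d.ordinal} on {d.protein_id!r}"
                )
            seen[key] = d


@dataclass
class SimilarityMatrix:
    """All-vs-all local-alignment scores and E-values over labelled domains."""

    labels: list[str]
    evalues: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("similarity matrix labels must be unique")
        self.evalues = np.asarray(self.evalues, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.evalues.shape != (n, n) or self.scores.shape != (n, n):
            raise ValidationError("similarity matrix shape does not match labels")
        if (self.evalues < 0).any():
            raise ValidationError("E-values must be non-negative")

    def classify(self, threshold: float = 1e-80) -> np.ndarray:
        """Boolean mask of cells with E-value strictly below ``threshold``."""
        return self.evalues < threshold


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    labels: list[str]
    rows: list[str]
    alphabet: str = "protein"  # protein | dna

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValidationError("Msa labels/rows length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("Msa labels must be unique")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValidationError("Msa rows have unequal lengths")
        if self.alphabet not in ("protein", "dna"):
            raise ValidationError(f"unknown Msa alphabet {self.alphabet!r}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, label: str) -> str:
        return self.rows[self.labels.index(label)].replace(GAP, "")

    def degapped_all(self) -> dict[str, str]:
        return {l: r.replace(GAP, "") for l, r in zip(self.labels, self.rows)}

    def columns(self) -> list[str]:
        return ["".join(r[j] for r in self.rows) for j in range(self.n_cols)]


@dataclass
class ElidedMatrix:
    """Concatenation of alignments of the same sequences under different
    gap costs, with a partition table recording each cost's column range."""

    msa: Msa
    partitions: list[tuple[str, int, int]]  # (name, start, end) half-open

    def __post_init__(self) -> None:
        pos = 0
        for name, s, e in self.partitions:
            if s != pos or e <= s:
                raise ValidationError(
                    f"partition {name!r} [{s}, {e}) does not tile the matrix"
                )
            pos = e
        if pos != self.msa.n_cols:
            raise ValidationError(
                f"partitions cover {pos} columns, matrix has {self.msa.n_cols}"
            )

    def partition_msa(self, name: str) -> Msa:
        for n, s, e in self.partitions:
            if n == name:
                return Msa(list(self.msa.labels),
                           [r[s:e] for r in self.msa.rows],
                           self.msa.alphabet)
        raise KeyError(name)
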