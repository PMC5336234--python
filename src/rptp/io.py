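"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (protein/DNA), GFF3-like exon tables, domain TSVs, Newick
files and labelled TSV matrices.  GFF coordinates are 1-based closed on disk
and converted to the internal 0-based half-open convention on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FastaParseError, GeneModelError, ValidationError
from .records import (AA_ALPHABET, DomainAnnotation, GeneModel, ProteinRecord,
                      SimilarityMatrix)
from .tree import Tree, read_newick, write_newick  # noqa: F401  (re-export)


# ---------------------------------------------------------------- FASTA

def _parse_fasta(path: str | os.PathLike, alphabet: frozenset[str]
                 ) -> list[tuple[str, str, str]]:
    """Shared FASTA reader: (id, sequence, description) tuples, validated."""
    header_lines: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                rid = line[1:].split()[0] if line[1:].split() else ""
                header_lines.setdefault(rid, i)
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        line_no = header_lines.get(rec.id, 0)
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r} (line {line_no})")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: empty sequence for {rec.id!r} (line {line_no})")
        bad = set(seq) - alphabet
        if bad:
            raise FastaParseError(
                f"{path}: illegal characters {sorted(bad)!r} in {rec.id!r} (line {line_no})"
            )
        out.append((rec.id, seq, rec.description[len(rec.id):].strip()))
    if not out:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Order is preserved and sequences are uppercased.  Duplicate ids and
    illegal residue characters raise :class:`FastaParseError` naming the
    offending record and its header line.
    """
    return [ProteinRecord(id=rid, sequence=seq, source=desc)
            for rid, seq, desc in _parse_fasta(path, AA_ALPHABET)]


def read_dna_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a DNA FASTA (e.g. in-frame CDS) as an ``{id: sequence}`` mapping."""
    return {rid: seq for rid, seq, _ in _parse_fasta(path, frozenset("ACGTN"))}


def read_alignment_fasta(path: str | os.PathLike, alphabet: str = "protein"):
    """Read an aligned FASTA (gap characters allowed) as an :class:`Msa`."""
    from .records import Msa
    allowed = (AA_ALPHABET if alphabet == "protein" else frozenset("ACGTN")) \
        | {"-"}
    rows = _parse_fasta(path, frozenset(allowed))
    return Msa([r[0] for r in rows], [r[1] for r in rows], alphabet=alphabet)


def write_fasta(records: Iterable[ProteinRecord] | dict[str, str],
                path: str | os.PathLike, width: int = 60) -> None:
    """Write records (or an ``{id: seq}`` mapping) as wrapped FASTA."""
    if isinstance(records, dict):
        items = list(records.items())
    else:
        items = [(r.id, r.sequence) for r in records]
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------- gene models

def read_gene_models(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read a GFF3-like exon table into gene models keyed by protein id.

    Expected columns (tab-separated, ``#`` comments ignored):
    seqid, source, type, start, end, score, strand, frame, attributes.
    Rows of type ``exon`` or ``CDS`` are used; the attributes field must
    contain ``protein_id=...``.  Coordinates are 1-based closed in the file.
    Minus-strand genes are flipped to transcript orientation.  Frame
    consistency (CDS length divisible by 3) is enforced per gene.
    """
    rows: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GeneModelError(f"{path}:{i}: expected 9 columns, got {len(parts)}")
            _, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in ("exon", "CDS"):
                continue
            pid = None
            for kv in attrs.replace(" ", "").split(";"):
                if kv.startswith("protein_id="):
                    pid = kv.split("=", 1)[1]
            if pid is None:
                raise GeneModelError(f"{path}:{i}: attributes lack protein_id=")
            rows.setdefault(pid, []).append((int(start), int(end), strand))

    models: dict[str, GeneModel] = {}
    for pid, feats in rows.items():
        strands = {s for _, _, s in feats}
        if len(strands) != 1:
            raise GeneModelError(f"gene {pid!r}: mixed strands")
        strand = strands.pop()
        # GFF 1-based closed -> 0-based half-open
        exons = sorted((s - 1, e) for s, e, _ in feats)
        if strand == "-":
            exons = exons[::-1]
        gm = GeneModel(protein_id=pid, exons=exons, strand=strand)
        gm.validate_frame()
        models[pid] = gm
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | os.PathLike,
                      seqid: str | None = None) -> None:
    """Write gene models as a GFF3-like exon table (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            sid = seqid or f"{gm.protein_id}_locus"
            exons = gm.exons if gm.strand == "+" else gm.exons[::-1]
            for s, e in sorted(exons):
                fh.write(
                    f"{sid}\trptp\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                    f"protein_id={gm.protein_id}\n"
                )


# -------------------------------------------------------------- domains

def read_domains(path: str | os.PathLike) -> list[DomainAnnotation]:
    """Read a domain TSV: protein_id, kind, start, end, ordinal ('' for none).

    Coordinates in the file are 0-based half-open (internal convention);
    this is a package-native table, not a GFF.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "kind": str})
    needed = {"protein_id", "kind", "start", "end"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: domain table needs columns {sorted(needed)}")
    out = []
    for _, row in df.iterrows():
        ordinal = row.get("ordinal")
        ordinal = None if pd.isna(ordinal) else int(ordinal)
        out.append(DomainAnnotation(
            protein_id=row["protein_id"], kind=row["kind"],
            start=int(row["start"]), end=int(row["end"]), ordinal=ordinal))
    return out


def write_domains(domains: Sequence[DomainAnnotation], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(d.protein_id, d.kind, d.start, d.end,
          "" if d.ordinal is None else d.ordinal) for d in domains],
        columns=["protein_id", "kind", "start", "end", "ordinal"])
    df.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- matrices

def write_matrix_tsv(labels: Sequence[str], matrix: np.ndarray,
                     path: str | os.PathLike) -> None:
    """Square matrix as TSV with a header row and a label column."""
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", index_label="label")


def read_matrix_tsv(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)


def write_similarity(matrix: SimilarityMatrix, out_prefix: str,
                     threshold: float = 1e-80) -> None:
    """E-value matrix, score matrix and below-threshold classification."""
    write_matrix_tsv(matrix.labels, matrix.evalues, out_prefix + ".evalues.tsv")
    write_matrix_tsv(matrix.labels, matrix.scores, out_prefix + ".scores.tsv")
    write_matrix_tsv(matrix.labels, matrix.classify(threshold).astype(int),
                     out_prefix + ".below_threshold.tsv")


# ---------------------------------------------------------------- trees

def read_newick_file(path: str | os.PathLike) -> Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick_file(tree: Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")
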