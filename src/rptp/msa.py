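"""Progressive multiple alignment under a gap-cost sweep, elision of the
resulting alignments into a partitioned supermatrix, and protein-guided
codon alignment of the corresponding coding sequences.

The alignment strategy is deliberately plain: a neighbor-joining guide tree
on pairwise alignment distances (d = 1 - identity), then profile-profile
global alignment with affine gaps up the guide tree.  The scientific payload
is the sweep-and-elide protocol — the same sequences aligned at several gap
costs, concatenated column-wise into one supermatrix partitioned by cost —
not any particular aligner's heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import align as _align
from .errors import AlignmentError, ValidationError
from .records import ElidedMatrix, Msa, ProteinRecord
from .tree import Clade, Tree

CODON_GAP = "---"

#: Standard codon table (DNA, no ambiguity) used for guided back-translation.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; a trailing stop codon is dropped."""
    if len(cds) % 3 != 0:
        raise AlignmentError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        aa = _CODON_TABLE.get(codon, "X")
        if aa == "*":
            if i == len(cds) - 3:
                break
            raise AlignmentError(f"internal stop codon at nucleotide {i}")
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class GapCostSweep:
    """The one-dimensional gap-cost sweep.

    ``costs`` are gap-open penalties; gap-extend is tied to open by
    ``extend_ratio`` with an absolute floor so the sweep stays
    one-dimensional.
    """

    costs: tuple[float, ...] = (1, 2, 4, 6, 8, 16)
    extend_ratio: float = 0.1
    min_extend: float = 0.5

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.costs):
            raise ValidationError("gap costs must be positive")
        if list(self.costs) != sorted(set(self.costs)):
            raise ValidationError("gap costs must be strictly increasing")

    def extend(self, cost: float) -> float:
        return max(cost * self.extend_ratio, self.min_extend)

    def label(self, cost: float) -> str:
        return f"gc{cost:g}"


# ------------------------------------------------------ guide tree (NJ)

def _nj_guide(labels: list[str], dist: dict[tuple[str, str], float]) -> Clade:
    """Neighbor joining with deterministic tie-breaks (smallest Q, then
    lexicographically smallest label pair).  Returns a rooted binary clade
    structure usable as a join order."""
    nodes: dict[str, Clade] = {l: Clade(label=l) for l in labels}
    active = sorted(labels)
    d = {(a, b): dist[(a, b)] if (a, b) in dist else dist[(b, a)]
         for a in active for b in active if a != b}

    while len(active) > 2:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[(a, b)] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        new = f"({a},{b})"
        nodes[new] = Clade(children=[nodes[a], nodes[b]])
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(new, c)] = d[(c, new)] = dn
        active = sorted([c for c in active if c not in (a, b)] + [new])
    a, b = active
    return Clade(children=[nodes[a], nodes[b]])


def pairwise_distances(seqs: list[ProteinRecord], matrix: str = "BLOSUM62"
                       ) -> dict[tuple[str, str], float]:
    """Guide-tree distances d = 1 - identity from exact global alignments.

    Independent of the gap-cost sweep, so they are computed once per
    sequence set and shared across the sweep."""
    by_id = {s.id: s.sequence for s in seqs}
    labels = sorted(by_id)
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dist[(a, b)] = 1.0 - _align.pairwise_identity(by_id[a], by_id[b],
                                                          matrix)
    return dist


def progressive_align(seqs: list[ProteinRecord], gap_open: float = 4.0,
                      gap_extend: float = 0.5, matrix: str = "BLOSUM62",
                      distances: dict[tuple[str, str], float] | None = None
                      ) -> Msa:
    """Progressive protein alignment: NJ guide tree, then profile merging.

    Deterministic for a given input: pairwise distances are exact global
    alignments, NJ ties break lexicographically by label, and DP tie-breaks
    are fixed.  Aligning a permuted input yields the same columns (row order
    follows guide-tree traversal, so re-sort rows to compare).
    """
    if not seqs:
        raise ValidationError("no sequences to align")
    if len(seqs) == 1:
        warnings.warn("progressive_align called with a single sequence")
        return Msa([seqs[0].id], [seqs[0].sequence])
    by_id = {s.id: s.sequence for s in seqs}
    if len(by_id) != len(seqs):
        raise ValidationError("duplicate sequence ids")
    labels = sorted(by_id)
    dist = distances if distances is not None else pairwise_distances(seqs, matrix)
    guide = _nj_guide(labels, dist) if len(labels) > 2 else Clade(
        children=[Clade(label=labels[0]), Clade(label=labels[1])])

    def merge(node: Clade) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [by_id[node.label]]
        (la, ra), (lb, rb) = merge(node.children[0]), merge(node.children[1])
        na, nb = _align.profile_align(ra, rb, matrix, gap_open, gap_extend)
        return la + lb, na + nb

    out_labels, rows = merge(guide)
    msa = Msa(out_labels, rows)
    for lbl in out_labels:
        if msa.degapped(lbl) != by_id[lbl]:
            raise AlignmentError(f"alignment corrupted sequence {lbl!r}")
    return msa


def sweep_align(seqs: list[ProteinRecord], sweep: GapCostSweep = GapCostSweep(),
                matrix: str = "BLOSUM62") -> list[tuple[str, Msa]]:
    """Align the same sequences at every gap cost of the sweep, in order.

    The guide-tree distances do not depend on the gap cost and are computed
    once for the whole sweep."""
    dist = pairwise_distances(seqs, matrix) if len(seqs) > 2 else None
    return [(sweep.label(c),
             progressive_align(seqs, gap_open=float(c),
                               gap_extend=sweep.extend(c), matrix=matrix,
                               distances=dist))
            for c in sweep.costs]


# --------------------------------------------------------------- elision

def elide(alignments: list[tuple[str, Msa]] | list[Msa]) -> ElidedMatrix:
    """Concatenate alignments of the same sequences into a supermatrix.

    Columns are concatenated in input order; the partition table records
    each input's (half-open) column range.  Every input must contain the
    same labels with the same underlying (degapped) sequences.
    """
    if not alignments:
        raise ValidationError("nothing to elide")
    named: list[tuple[str, Msa]] = []
    for k, item in enumerate(alignments):
        if isinstance(item, Msa):
            named.append((f"part{k + 1}", item))
        else:
            named.append(item)
    ref_name, ref = named[0]
    ref_seqs = ref.degapped_all()
    label_order = list(ref.labels)
    for name, m in named[1:]:
        if set(m.labels) != set(label_order):
            raise ValidationError(f"alignment {name!r}: label set mismatch")
        for lbl, seq in m.degapped_all().items():
            if seq != ref_seqs[lbl]:
                raise ValidationError(
                    f"alignment {name!r}: sequence mismatch for {lbl!r}")
    rows = {lbl: [] for lbl in label_order}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for name, m in named:
        for lbl in label_order:
            rows[lbl].append(m.rows[m.labels.index(lbl)])
        partitions.append((name, pos, pos + m.n_cols))
        pos += m.n_cols
    super_msa = Msa(label_order, ["".join(rows[lbl]) for lbl in label_order],
                    alphabet=ref.alphabet)
    return ElidedMatrix(msa=super_msa, partitions=partitions)


def write_partitions(elided: ElidedMatrix, path: str,
                     datatype: str = "PROT") -> None:
    """RAxML-style partition file (1-based closed column ranges)."""
    with open(path, "w") as fh:
        for name, s, e in elided.partitions:
            fh.write(f"{datatype}, {name} = {s + 1}-{e}\n")


def write_nexus_charsets(elided: ElidedMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin sets;\n")
        for name, s, e in elided.partitions:
            fh.write(f"    charset {name} = {s + 1}-{e};\n")
        fh.write("end;\n")


# -------------------------------------------------- guided codon alignment

def backtranslate(protein_msa: Msa, cds: dict[str, str],
                  stop_included: bool = True) -> Msa:
    """Convert a protein alignment into a codon alignment of its CDS.

    Each amino-acid column becomes a codon triple; protein gaps become
    ``---``.  Every CDS must translate exactly to its degapped protein row
    (a trailing stop is allowed when ``stop_included``); any nonsynonymous
    mismatch raises an error naming the label and the first bad residue.
    """
    rows_out = []
    for lbl, row in zip(protein_msa.labels, protein_msa.rows):
        if lbl not in cds:
            raise ValidationError(f"no CDS for {lbl!r}")
        dna = cds[lbl].upper()
        protein = row.replace("-", "")
        trans = translate_cds(dna)  # drops a trailing stop codon
        if not stop_included and len(dna) == 3 * len(protein) + 3:
            raise AlignmentError(f"{lbl!r}: unexpected stop codon in CDS")
        if len(trans) != len(protein):
            raise AlignmentError(
                f"{lbl!r}: CDS translates to {len(trans)} residues, protein "
                f"row has {len(protein)}")
        for i, (x, y) in enumerate(zip(trans, protein)):
            if x != y and "X" not in (x, y):
                raise AlignmentError(
                    f"{lbl!r}: translation mismatch at residue {i} "
                    f"({x!r} from CDS vs {y!r} in alignment)")
        codons = [dna[3 * i:3 * i + 3] for i in range(len(protein))]
        out = []
        k = 0
        for ch in row:
            if ch == "-":
                out.append(CODON_GAP)
            else:
                out.append(codons[k])
                k += 1
        rows_out.append("".join(out))
    return Msa(list(protein_msa.labels), rows_out, alphabet="dna")
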