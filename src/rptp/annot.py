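"""Structural character systems of the R3 RPTP family.

Four character systems are computed per protein and later mapped onto the
phylogeny:

* **B-C loop WnGnY codes** — each FN3 repeat carries a conserved tryptophan
  in β-strand B and a tyrosine in β-strand C delimiting the B-C loop, with
  a conserved glycine inside it.  The code ``W{n}G{m}Y`` records the number
  of residues strictly between W and G (n) and between G and Y (m), and is
  mapped to the standard colour classes (red = W4G4Y, dark blue = W7G4Y, ...).
* **FN3 intron-phase codes** — the phases of the introns flanking and
  interrupting each FN3 repeat, e.g. ``1:1`` (one exon, phase-1 flanks) or
  ``1:0:1`` (an extra internal phase-0 intron).
* **WPD-loop calls** — the catalytic motif-8 triplet of the PTP domain;
  the D→E replacement (WPE) switches substrate specificity from
  phosphotyrosine to phosphoinositides.
* **C-terminal YxN motifs** — tyrosines after the PTP domain, classified by
  whether the +2 residue is asparagine (the reported phosphorylation motif).

Residue landmarks (W/G/Y, the WPD triplet) are placed by globally aligning
each domain to a reference scaffold and reading the residues in the
scaffold's landmark columns.  The shipped scaffolds are synthetic
constructions with declared landmark columns (see ``data/``); any scaffold
with landmarks can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .align import global_affine
from .errors import ValidationError
from .records import DomainAnnotation, GeneModel, ProteinRecord

#: Fig-style colour classes for B-C loop codes; anything else is white.
BCLOOP_COLORS = {
    "W4G4Y": "red",
    "W4G5Y": "orange",
    "W4G7Y": "light blue",
    "W5G4Y": "green",
    "W7G3Y": "yellow",
    "W7G4Y": "dark blue",
    "W9G2Y": "lavender",
    "W9G4Y": "pink",
}

#: Colour classes for FN3 intron codes; grey is the long juxtamembrane
#: multi-intron pattern, anything else unlisted is white.
INTRON_COLORS = {
    "1:1": "yellow",
    "1:0:1": "orange",
    "1:1:1": "blue",
    "1:2:1": "black",
}

MAX_LOOP_LEN = 30  # B-C loops are short; a longer W..Y span means a misanchor


# ------------------------------------------------------------- scaffolds

@dataclass(frozen=True)
class ReferenceScaffold:
    """A reference domain sequence with named landmark columns.

    ``landmarks`` maps a landmark name to a 0-based position in
    ``sequence``.  Multi-column landmarks (the WPD triplet) are stored by
    their first column.
    """

    name: str
    sequence: str
    landmarks: dict[str, int]

    def __post_init__(self) -> None:
        for lm, pos in self.landmarks.items():
            if not (0 <= pos < len(self.sequence)):
                raise ValidationError(
                    f"scaffold {self.name!r}: landmark {lm!r} out of range")


def _load_scaffold(fasta_name: str, scaffold_name: str) -> ReferenceScaffold:
    data = resources.files("rptp.data")
    seq_lines = (data / fasta_name).read_text().splitlines()
    seq = "".join(l.strip() for l in seq_lines if not l.startswith(">"))
    lm_text = (data / "scaffold_landmarks_synthetic.tsv").read_text()
    landmarks = {}
    for line in lm_text.splitlines()[1:]:
        scaf, lm, pos = line.split("\t")
        if scaf == scaffold_name:
            landmarks[lm] = int(pos)
    return ReferenceScaffold(scaffold_name, seq, landmarks)


def fn3_scaffold() -> ReferenceScaffold:
    """The shipped (synthetic) FN3 reference with W/G/Y landmarks."""
    return _load_scaffold("fn3_scaffold_synthetic.fasta", "FN3_ref")


def ptp_scaffold() -> ReferenceScaffold:
    """The shipped (synthetic) PTP-domain reference with the WPD landmark."""
    return _load_scaffold("ptp_scaffold_synthetic.fasta", "PTP_ref")


# ------------------------------------------------------------ anchoring

def _aligned_positions(domain_seq: str, scaffold: ReferenceScaffold,
                       positions: list[int]) -> dict[int, int | None]:
    """Map scaffold columns to domain positions via global alignment.

    A scaffold column aligned to a gap maps to None.  No residue-identity
    requirement here; callers add one where the landmark demands it.
    """
    _, row_s, row_d = global_affine(scaffold.sequence, domain_seq)
    wanted = set(positions)
    out: dict[int, int | None] = {}
    si = di = 0
    for cs, cd in zip(row_s, row_d):
        if cs != "-" and si in wanted:
            out[si] = di if cd != "-" else None
        if cs != "-":
            si += 1
        if cd != "-":
            di += 1
    for p in positions:
        out.setdefault(p, None)
    return out


def anchor_landmarks(domain_seq: str, scaffold: ReferenceScaffold
                     ) -> dict[str, int | None]:
    """Place each scaffold landmark on a domain sequence.

    A landmark maps to the domain residue aligned to its scaffold column;
    it is absent (None) when that column aligns to a gap or the residue
    fails the identity check (a W landmark must be W, etc.).  Multi-column
    landmarks such as WPD are placed by their first column with no identity
    requirement (the triplet is allowed to vary — that is the character).
    """
    pos_map = _aligned_positions(domain_seq, scaffold,
                                 list(scaffold.landmarks.values()))
    out: dict[str, int | None] = {}
    for lm, spos in scaffold.landmarks.items():
        dpos = pos_map[spos]
        if dpos is not None and len(lm) == 1 and domain_seq[dpos] != lm:
            dpos = None
        out[lm] = dpos
    return out


# --------------------------------------------------------- B-C loop code

@dataclass
class BCLoopCode:
    """WnGnY classification of one FN3 B-C loop."""

    protein_id: str
    fn3_ordinal: int | None
    w_pos: int | None
    g_pos: int | None
    y_pos: int | None
    code: str
    color: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.w_pos is not None and self.g_pos is not None and self.y_pos is not None:
            if not (self.w_pos < self.g_pos < self.y_pos):
                raise ValidationError(
                    f"{self.protein_id}: landmark order violated")


def bcloop_code(domain_seq: str, scaffold: ReferenceScaffold | None = None,
                protein_id: str = "", fn3_ordinal: int | None = None
                ) -> BCLoopCode:
    """Classify the B-C loop of one FN3 domain sequence.

    The W and Y anchors come from scaffold alignment.  The glycine is the
    loop G aligned to the scaffold's loop-G column when that is a G inside
    the loop; otherwise the leftmost G strictly between W and Y.  Domains
    with a missing anchor, an overlong loop, or no loop glycine are coded
    white (the no-G case uses the code ``W{L}Y`` with L the loop length).
    """
    scaffold = scaffold or fn3_scaffold()
    lm = anchor_landmarks(domain_seq, scaffold)
    w, y = lm.get("W"), lm.get("Y")
    if w is None or y is None:
        missing = [k for k in ("W", "Y") if lm.get(k) is None]
        return BCLoopCode(protein_id, fn3_ordinal, w, None, y, code="",
                          color="white",
                          reason=f"missing {'/'.join(missing)} anchor")
    if not w < y:
        return BCLoopCode(protein_id, fn3_ordinal, None, None, None, code="",
                          color="white", reason="anchors out of order")
    loop_len = y - w - 1
    if loop_len > MAX_LOOP_LEN:
        return BCLoopCode(protein_id, fn3_ordinal, None, None, None, code="",
                          color="white",
                          reason=f"loop length {loop_len} exceeds {MAX_LOOP_LEN}")
    g = None
    g_scaf = scaffold.landmarks.get("G")
    if g_scaf is not None:
        mapped = _aligned_positions(domain_seq, scaffold, [g_scaf])[g_scaf]
        if mapped is not None and w < mapped < y and domain_seq[mapped] == "G":
            g = mapped
    if g is None:
        for p in range(w + 1, y):
            if domain_seq[p] == "G":
                g = p
                break
    if g is None:
        return BCLoopCode(protein_id, fn3_ordinal, w, None, y,
                          code=f"W{loop_len}Y", color="white",
                          reason="no glycine in loop")
    n, m = g - w - 1, y - g - 1
    code = f"W{n}G{m}Y"
    return BCLoopCode(protein_id, fn3_ordinal, w, g, y, code=code,
                      color=BCLOOP_COLORS.get(code, "white"))


# -------------------------------------------------------- intron phases

def intron_phases(gene: GeneModel) -> list[tuple[int, int]]:
    """(protein_position, phase) for every intron of a gene model.

    For the intron after a cumulative coding length of c nucleotides:
    phase = c mod 3 and protein_position = c // 3.  A phase-0 junction
    precedes residue c//3; phases 1 and 2 interrupt that residue.
    Positions are 0-based.
    """
    gene.validate_frame()
    out = []
    c = 0
    for length in gene.cds_lengths[:-1]:
        c += length
        out.append((c // 3, c % 3))
    return out


@dataclass
class IntronPatternCode:
    """Intron-phase pattern of one FN3 domain: flanking phases, internal
    phases, the colon-joined code, and its colour class."""

    protein_id: str
    fn3_ordinal: int | None
    upstream_phase: int | None     # None = absent flank
    internal: list[int]
    downstream_phase: int | None
    code: str
    color: str
    open_upstream: bool = False
    open_downstream: bool = False


def fn3_intron_code(domain: DomainAnnotation,
                    phases: list[tuple[int, int]],
                    prev_boundary: int | None = None,
                    next_boundary: int | None = None,
                    juxtamembrane: bool = False) -> IntronPatternCode:
    """Classify one FN3 domain by its intron-phase pattern.

    Introns strictly inside (start, end) are internal; an intron exactly on
    a boundary counts as the flank on that side.  The upstream/downstream
    flank is the nearest intron at or outside the span, searched no further
    than ``prev_boundary``/``next_boundary`` (neighbouring domain edges or
    protein ends); absent flanks are recorded as open sides, never as
    phase 0.  ``juxtamembrane`` marks the enlarged membrane-proximal domain
    whose multi-intron pattern is the grey class.
    """
    phases = sorted(phases)
    lo = prev_boundary if prev_boundary is not None else -1
    hi = next_boundary if next_boundary is not None else float("inf")
    internal = [ph for pos, ph in phases if domain.start < pos < domain.end]
    ups = [(pos, ph) for pos, ph in phases if lo <= pos <= domain.start]
    downs = [(pos, ph) for pos, ph in phases if domain.end <= pos <= hi]
    upstream = ups[-1][1] if ups else None
    downstream = downs[0][1] if downs else None
    parts = ([] if upstream is None else [str(upstream)]) + \
        [str(p) for p in internal] + \
        ([] if downstream is None else [str(downstream)])
    code = ":".join(parts)
    if juxtamembrane and len(internal) >= 2:
        color = "grey"
    elif upstream is None or downstream is None:
        color = "white"
    else:
        color = INTRON_COLORS.get(code, "white")
    return IntronPatternCode(
        protein_id=domain.protein_id, fn3_ordinal=domain.ordinal,
        upstream_phase=upstream, internal=internal, downstream_phase=downstream,
        code=code, color=color,
        open_upstream=upstream is None, open_downstream=downstream is None)


# ------------------------------------------------------------- WPD calls

@dataclass
class WPDCall:
    """The motif-8 (WPD-loop) triplet of a PTP domain and its class."""

    protein_id: str
    triplet: str
    cls: str  # WPD | WPE | other
    warning: str = ""

    def __post_init__(self) -> None:
        expected = self.triplet if self.triplet in ("WPD", "WPE") else "other"
        if self.cls != expected:
            raise ValidationError(
                f"{self.protein_id}: class {self.cls!r} inconsistent with "
                f"triplet {self.triplet!r}")


MIN_PTP_IDENTITY = 0.20


def call_wpd(ptp_domain_seq: str, scaffold: ReferenceScaffold | None = None,
             protein_id: str = "") -> WPDCall:
    """Read the WPD-loop triplet of a PTP domain by scaffold alignment.

    The three residues aligned to the scaffold's WPD columns form the
    triplet ('-' for gapped columns).  If overall alignment identity falls
    below 20% the anchor is unreliable and the call is 'other' with
    triplet '???'.
    """
    scaffold = scaffold or ptp_scaffold()
    wpd_start = scaffold.landmarks["WPD"]
    _, row_s, row_d = global_affine(scaffold.sequence, ptp_domain_seq)
    pairs = [(x, y) for x, y in zip(row_s, row_d) if x != "-" and y != "-"]
    identity = (sum(x == y for x, y in pairs) / len(pairs)) if pairs else 0.0
    if identity < MIN_PTP_IDENTITY:
        return WPDCall(protein_id, "???", "other",
                       warning=f"scaffold identity {identity:.2f} below "
                               f"{MIN_PTP_IDENTITY:.2f}; triplet not anchored")
    cols = _aligned_positions(ptp_domain_seq, scaffold,
                              [wpd_start, wpd_start + 1, wpd_start + 2])
    triplet = "".join(
        ptp_domain_seq[cols[p]] if cols[p] is not None else "-"
        for p in (wpd_start, wpd_start + 1, wpd_start + 2))
    cls = triplet if triplet in ("WPD", "WPE") else "other"
    return WPDCall(protein_id, triplet, cls)


# ------------------------------------------------------------ YxN motifs

@dataclass
class PhosphoMotifReport:
    """Tyrosines in the tail after the PTP domain, classified as YxN or
    other, optionally joined with externally supplied prediction scores."""

    protein_id: str
    tail_start: int
    motifs: list[tuple[int, str]]  # (y_pos, 'YxN' | 'otherY')
    external_scores: dict[int, float] = field(default_factory=dict)

    @property
    def pattern(self) -> str:
        """Summary: 'YxN' if any canonical motif, 'otherY' if only
        non-canonical tyrosines, 'none' if the tail has no tyrosine."""
        kinds = {k for _, k in self.motifs}
        if "YxN" in kinds:
            return "YxN"
        if kinds:
            return "otherY"
        return "none"


def scan_yxn(protein: ProteinRecord, ptp_end: int,
             external_scores: dict[int, float] | None = None
             ) -> PhosphoMotifReport:
    """Scan the region C-terminal to the PTP domain for tyrosine motifs.

    Every tyrosine at position p >= ptp_end is reported; it is a YxN motif
    iff position p+2 exists and carries asparagine.
    """
    if ptp_end > len(protein):
        raise ValidationError(
            f"{protein.id}: ptp_end {ptp_end} beyond protein length")
    seq = protein.sequence
    motifs = []
    for p in range(ptp_end, len(seq)):
        if seq[p] == "Y":
            kind = "YxN" if p + 2 < len(seq) and seq[p + 2] == "N" else "otherY"
            motifs.append((p, kind))
    return PhosphoMotifReport(protein.id, ptp_end, motifs,
                              external_scores or {})


# -------------------------------------------------- whole-protein table

def character_table(proteins: list[ProteinRecord],
                    domains: list[DomainAnnotation],
                    gene_models: dict[str, GeneModel] | None = None,
                    fn3_ref: ReferenceScaffold | None = None,
                    ptp_ref: ReferenceScaffold | None = None
                    ) -> pd.DataFrame:
    """One row per protein: WPD triplet/class, YxN pattern, and per-ordinal
    B-C loop and intron codes (missing data become '?')."""
    fn3_ref = fn3_ref or fn3_scaffold()
    ptp_ref = ptp_ref or ptp_scaffold()
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_protein.setdefault(d.protein_id, []).append(d)
    rows = []
    for prot in proteins:
        doms = sorted(by_protein.get(prot.id, []), key=lambda d: d.start)
        fn3s = [d for d in doms if d.kind == "FN3"]
        ptps = [d for d in doms if d.kind == "PTP"]
        row: dict[str, object] = {"protein_id": prot.id}
        if ptps:
            ptp = ptps[0]
            call = call_wpd(prot.sequence[ptp.start:ptp.end], ptp_ref, prot.id)
            row["wpd_triplet"], row["wpd_class"] = call.triplet, call.cls
            row["yxn_pattern"] = scan_yxn(prot, ptp.end).pattern
        else:
            row["wpd_triplet"] = row["wpd_class"] = row["yxn_pattern"] = "?"
        phases = None
        if gene_models and prot.id in gene_models:
            phases = intron_phases(gene_models[prot.id])
        for k, dom in enumerate(fn3s):
            bc = bcloop_code(prot.sequence[dom.start:dom.end], fn3_ref,
                             prot.id, dom.ordinal)
            row[f"bcloop_{dom.ordinal}"] = bc.code or "?"
            if phases is not None:
                prev_b = fn3s[k - 1].end if k > 0 else None
                next_b = fn3s[k + 1].start if k + 1 < len(fn3s) else None
                jm = bool(dom.ordinal == 1 and len(dom) > int(1.5 * len(fn3_ref.sequence)))
                code = fn3_intron_code(dom, phases, prev_b, next_b,
                                       juxtamembrane=jm)
                row[f"introns_{dom.ordinal}"] = code.code or "?"
            else:
                row[f"introns_{dom.ordinal}"] = "?"
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein_id")
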