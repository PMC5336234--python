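"""Synthetic R3-like gene families with planted, recoverable ground truth.

A family is evolved along a user-supplied tree (branch lengths in expected
substitutions per site).  The ancestral protein is assembled from the
package's reference scaffolds as a segment list — signal peptide, FN3
repeats, linkers, transmembrane helix, PTP domain, cytoplasmic tail — and
each clade ("group") can plant its own characters on the stem branch of its
most recent common ancestor:

* a B-C loop WnGnY code per FN3 ordinal,
* a WPD-loop triplet (WPD / WPE / anything),
* a tail motif plan (canonical YxN, a non-YxN tyrosine, or no tyrosine),
* an intron-phase pattern per FN3 ordinal,
* an enlarged juxtamembrane (ordinal-1) FN3 repeat.

Landmark sites are masked from substitution and the surrounding segment
alphabets exclude confusable residues (no stray W/G/Y inside FN3 repeats,
no Y/N in the tail), so the planted truth stays well defined.  Indels occur
only in inter-domain linkers.  Everything is driven by one seed; the same
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annot import MAX_LOOP_LEN, fn3_scaffold, ptp_scaffold
from .errors import ConfigError
from .msa import _CODON_TABLE
from .phylo import GroupDefinition
from .records import DomainAnnotation, GeneModel, ProteinRecord
from .tree import Clade, Tree

# preferred codon per amino acid, for emitting an in-frame CDS
_PREFERRED_CODON = {}
for codon, aa in sorted(_CODON_TABLE.items()):
    _PREFERRED_CODON.setdefault(aa, codon)

_FN3_FILLER = "ADEHIKLNPQRSTV"      # no W/G/Y/C: loops stay unambiguous
_TAIL_FILLER = "ADEHIKLPQRSTV"      # additionally no N: YxN stays planted
_GENERIC = "ACDEFGHIKLMNPQRSTVWY"

_INTRON_LEN = 120
_GENOMIC_OFFSET = 500


# ------------------------------------------------------------- planning

@dataclass(frozen=True)
class GroupPlan:
    """Planted characters for one clade.

    ``bcloop`` and ``introns`` map FN3 ordinal -> code ("W4G4Y"; "1:1",
    "1:0:1", "-:1" with '-' marking an absent flank).  ``tail`` is one of
    yxn / otherY / none.  ``juxtamembrane`` enlarges the ordinal-1 repeat.
    """

    name: str
    members: tuple[str, ...]
    bcloop: dict[int, str] = field(default_factory=dict)
    wpd: str = "WPD"
    tail: str = "yxn"
    introns: dict[int, str] = field(default_factory=dict)
    juxtamembrane: bool = False

    def validate(self, n_fn3: int) -> None:
        if len(self.wpd) != 3:
            raise ConfigError(f"group {self.name!r}: WPD plan must be a triplet")
        if self.tail not in ("yxn", "otherY", "none"):
            raise ConfigError(f"group {self.name!r}: bad tail plan {self.tail!r}")
        for o, code in self.bcloop.items():
            if not 1 <= o <= n_fn3:
                raise ConfigError(f"group {self.name!r}: no FN3 ordinal {o}")
            n, m = _parse_bcloop(code)
            if n + m + 1 > MAX_LOOP_LEN:
                raise ConfigError(
                    f"group {self.name!r}: loop code {code} needs "
                    f"{n + m + 1} residues, above the {MAX_LOOP_LEN} cap")
        for o, code in self.introns.items():
            _parse_intron_plan(code)


def _parse_bcloop(code: str) -> tuple[int, int]:
    m = re.fullmatch(r"W(\d+)G(\d+)Y", code)
    if not m:
        raise ConfigError(f"bad B-C loop code {code!r}")
    n, g = int(m.group(1)), int(m.group(2))
    if n < 1 or g < 1:
        raise ConfigError(f"loop code {code!r}: spacings must be >= 1")
    return n, g


def _parse_intron_plan(code: str) -> tuple[int | None, list[int], int | None]:
    parts = code.split(":")
    if len(parts) < 2:
        raise ConfigError(f"intron plan {code!r} needs at least two fields")

    def flank(tok: str) -> int | None:
        if tok == "-":
            return None
        if tok not in ("0", "1", "2"):
            raise ConfigError(f"bad intron phase {tok!r} in {code!r}")
        return int(tok)

    up, down = flank(parts[0]), flank(parts[-1])
    internal = []
    for tok in parts[1:-1]:
        if tok not in ("0", "1", "2"):
            raise ConfigError(f"bad internal phase {tok!r} in {code!r}")
        internal.append(int(tok))
    return up, internal, down


@dataclass
class SimConfig:
    """Study conditions for one simulated family."""

    tree: str
    groups: list[GroupPlan]
    root_plan: GroupPlan
    n_fn3: int = 3
    subst_rate: float = 1.0
    indel_rate: float = 0.05
    seed: int = 42

    def validate(self) -> Tree:
        t = Tree.from_newick(self.tree)
        leaves = set(t.leaf_labels())
        seen: set[str] = set()
        for g in self.groups:
            g.validate(self.n_fn3)
            members = set(g.members)
            if not members <= leaves:
                raise ConfigError(f"group {g.name!r}: members not in tree")
            if members & seen:
                raise ConfigError(f"group {g.name!r}: overlapping members")
            seen |= members
        self.root_plan.validate(self.n_fn3)
        if self.subst_rate < 0 or self.indel_rate < 0:
            raise ConfigError("rates must be non-negative")
        return t


#: Tree used by the default study conditions: five vertebrate clades
#: (three species each), two tunicate singletons, a protostome and a sponge
#: outgroup; internal stems around 0.15-0.3 expected substitutions/site.
DEFAULT_TREE = (
    "(Sponge:0.5,(Protostome:0.45,"
    "((Ciona_2:0.35,(Hs_PTPRQ:0.1,(Mm_PTPRQ:0.08,Dr_PTPRQ:0.12):0.05):0.3):0.3,"
    "((Ciona_1:0.35,(Hs_PTPRB:0.1,(Mm_PTPRB:0.08,Dr_PTPRB:0.12):0.05):0.3):0.2,"
    "((Hs_PTPRO:0.1,(Mm_PTPRO:0.08,Dr_PTPRO:0.12):0.05):0.3,"
    "((Hs_PTPRJ:0.1,(Mm_PTPRJ:0.08,Dr_PTPRJ:0.12):0.05):0.25,"
    "(Hs_PTPRH:0.1,(Mm_PTPRH:0.08,Dr_PTPRH:0.12):0.05):0.25):0.15):0.1):0.15)"
    ":0.2):0.1);"
)


def default_config(seed: int = 42) -> SimConfig:
    """The default study conditions: one clade per vertebrate R3 group with
    its characteristic planted characters, plus tunicate/protostome/sponge
    outgroups."""
    def trio(g: str) -> tuple[str, ...]:
        return (f"Hs_{g}", f"Mm_{g}", f"Dr_{g}")

    groups = [
        GroupPlan("PTPRB", trio("PTPRB"), bcloop={o: "W4G4Y" for o in (1, 2, 3)},
                  wpd="WPD", tail="yxn", introns={o: "1:1" for o in (1, 2, 3)},
                  juxtamembrane=True),
        GroupPlan("PTPRJ", trio("PTPRJ"), bcloop={o: "W4G5Y" for o in (1, 2, 3)},
                  wpd="WPD", tail="yxn", introns={o: "1:1" for o in (1, 2, 3)},
                  juxtamembrane=True),
        GroupPlan("PTPRH", trio("PTPRH"), bcloop={o: "W5G4Y" for o in (1, 2, 3)},
                  wpd="WPD", tail="yxn", introns={o: "1:1" for o in (1, 2, 3)}),
        GroupPlan("PTPRO", trio("PTPRO"), bcloop={o: "W4G7Y" for o in (1, 2, 3)},
                  wpd="WPD", tail="yxn", introns={o: "1:0:1" for o in (1, 2, 3)}),
        GroupPlan("PTPRQ", trio("PTPRQ"), bcloop={o: "W7G4Y" for o in (1, 2, 3)},
                  wpd="WPE", tail="none",
                  introns={3: "1:2:1", 2: "1:2:1", 1: "1:1:2:1"},
                  juxtamembrane=True),
        GroupPlan("Ciona_1", ("Ciona_1",), bcloop={o: "W4G4Y" for o in (1, 2, 3)},
                  wpd="WPD", tail="yxn", introns={o: "1:1" for o in (1, 2, 3)},
                  juxtamembrane=True),
        GroupPlan("Ciona_2", ("Ciona_2",), bcloop={o: "W7G4Y" for o in (1, 2, 3)},
                  wpd="WSV", tail="none", introns={o: "1:2:1" for o in (1, 2, 3)},
                  juxtamembrane=True),
        GroupPlan("Protostome", ("Protostome",),
                  bcloop={o: "W4G4Y" for o in (1, 2, 3)},
                  wpd="WPD", tail="otherY",
                  introns={o: "1:1" for o in (1, 2, 3)}),
        GroupPlan("Sponge", ("Sponge",), bcloop={o: "W4G4Y" for o in (1, 2, 3)},
                  wpd="WPD", tail="yxn", introns={o: "1:1" for o in (1, 2, 3)}),
    ]
    root = GroupPlan("root", (), bcloop={o: "W4G4Y" for o in (1, 2, 3)},
                     wpd="WPD", tail="yxn",
                     introns={o: "1:1" for o in (1, 2, 3)})
    return SimConfig(tree=DEFAULT_TREE, groups=groups, root_plan=root,
                     seed=seed)


# -------------------------------------------------------------- segments

@dataclass
class _Segment:
    role: str                 # sp | fn3 | linker | tm | ptp | tail
    residues: list[str]
    mutable: list[bool]
    alphabet: str
    meta: dict = field(default_factory=dict)

    def copy(self) -> "_Segment":
        return _Segment(self.role, list(self.residues), list(self.mutable),
                        self.alphabet, dict(self.meta))


def _filler(rng: np.random.Generator, k: int, alphabet: str) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=k)]


def _fn3_segment(code: str, rng: np.random.Generator,
                 enlarged: bool = False) -> _Segment:
    """An FN3 repeat built on the reference scaffold with the planted loop.

    The W/G/Y landmarks, the whole loop and two flanking residues on each
    side are masked from substitution; the enlarged (juxtamembrane) variant
    carries 60 extra mutable residues after strand C.
    """
    scaffold = fn3_scaffold()
    seq = scaffold.sequence
    w, y = scaffold.landmarks["W"], scaffold.landmarks["Y"]
    n, m = _parse_bcloop(code)
    prefix = list(seq[:w])
    loop = ["W"] + _filler(rng, n, _FN3_FILLER) + ["G"] + \
        _filler(rng, m, _FN3_FILLER) + ["Y"]
    suffix = list(seq[y + 1:])
    if enlarged:
        suffix = suffix[:6] + _filler(rng, 60, _FN3_FILLER) + suffix[6:]
    residues = prefix + loop + suffix
    mutable = [True] * len(residues)
    for i in range(len(prefix) - 2, len(prefix) + len(loop) + 2):
        if 0 <= i < len(residues):
            mutable[i] = False
    return _Segment("fn3", residues, mutable, _FN3_FILLER,
                    meta={"loop_start": len(prefix),
                          "loop_end": len(prefix) + len(loop) - 1,
                          "code": code, "enlarged": enlarged})


def _ptp_segment(wpd: str, rng: np.random.Generator) -> _Segment:
    scaffold = ptp_scaffold()
    seq = list(scaffold.sequence)
    off = scaffold.landmarks["WPD"]
    seq[off:off + 3] = list(wpd)
    mutable = [True] * len(seq)
    for i in range(off - 2, off + 5):
        mutable[i] = False
    return _Segment("ptp", seq, mutable, _GENERIC,
                    meta={"wpd_offset": off, "wpd": wpd})


def _tail_segment(kind: str, rng: np.random.Generator) -> _Segment:
    pre = _filler(rng, 10, _TAIL_FILLER)
    post = _filler(rng, 12, _TAIL_FILLER)
    if kind == "yxn":
        motif = ["Y", "A", "N"]
    elif kind == "otherY":
        motif = ["Y", "A", "Q"]
    else:
        motif = _filler(rng, 3, _TAIL_FILLER)
    residues = pre + motif + post
    mutable = [True] * len(residues)
    for i in range(len(pre), len(pre) + 3):
        mutable[i] = False
    return _Segment("tail", residues, mutable, _TAIL_FILLER,
                    meta={"kind": kind})


def _build_ancestor(plan: GroupPlan, n_fn3: int,
                    rng: np.random.Generator) -> list[_Segment]:
    segments: list[_Segment] = []
    sp = ["M"] + _filler(rng, 17, "ALVFIS")
    segments.append(_Segment("sp", sp, [False] + [True] * 17, "ALVFIS"))
    for ordinal in range(n_fn3, 0, -1):  # N-terminal repeat has the highest
        code = plan.bcloop.get(ordinal, "W4G4Y")
        enlarged = plan.juxtamembrane and ordinal == 1
        segments.append(_fn3_segment(code, rng, enlarged))
        segments[-1].meta["ordinal"] = ordinal
        segments.append(_Segment("linker", _filler(rng, 8, _GENERIC),
                                 [True] * 8, _GENERIC))
    tm = list("LLIAVGLGLALLVILIAVLG") + ["R", "R", "K"]
    segments.append(_Segment("tm", tm, [True] * len(tm), "ALVFIGM"))
    segments.append(_ptp_segment(plan.wpd, rng))
    segments.append(_tail_segment(plan.tail, rng))
    return segments


# -------------------------------------------------------------- evolution

def _evolve_branch(segments: list[_Segment], t: float, subst_rate: float,
                   indel_rate: float, rng: np.random.Generator) -> None:
    p = 1.0 - np.exp(-subst_rate * t)
    for seg in segments:
        k = len(seg.residues)
        hits = rng.random(k) < p
        for i in np.flatnonzero(hits):
            if not seg.mutable[i]:
                continue
            cur = seg.residues[i]
            choices = [a for a in seg.alphabet if a != cur]
            seg.residues[i] = choices[rng.integers(0, len(choices))]
        if seg.role == "linker" and rng.random() < indel_rate * t:
            if rng.random() < 0.5 and len(seg.residues) > 4:
                at = int(rng.integers(0, len(seg.residues) - 2))
                del seg.residues[at:at + 2]
                del seg.mutable[at:at + 2]
            else:
                at = int(rng.integers(0, len(seg.residues)))
                ins = _filler(rng, int(rng.integers(1, 4)), seg.alphabet)
                seg.residues[at:at] = ins
                seg.mutable[at:at] = [True] * len(ins)


def _apply_plan(segments: list[_Segment], plan: GroupPlan,
                rng: np.random.Generator) -> None:
    """Rewrite planted characters on a group's stem branch."""
    for seg in segments:
        if seg.role == "fn3":
            ordinal = seg.meta["ordinal"]
            code = plan.bcloop.get(ordinal)
            enlarged = plan.juxtamembrane and ordinal == 1
            if code is not None and (code != seg.meta["code"]
                                     or enlarged != seg.meta["enlarged"]):
                new = _fn3_segment(code, rng, enlarged)
                new.meta["ordinal"] = ordinal
                seg.residues, seg.mutable = new.residues, new.mutable
                seg.meta = new.meta
                seg.meta["ordinal"] = ordinal
        elif seg.role == "ptp" and plan.wpd != seg.meta["wpd"]:
            off = seg.meta["wpd_offset"]
            seg.residues[off:off + 3] = list(plan.wpd)
            seg.meta["wpd"] = plan.wpd
        elif seg.role == "tail" and plan.tail != seg.meta["kind"]:
            new = _tail_segment(plan.tail, rng)
            seg.residues, seg.mutable, seg.meta = \
                new.residues, new.mutable, new.meta


# ------------------------------------------------------------- emission

def _domains_for(leaf: str, segments: list[_Segment]
                 ) -> list[DomainAnnotation]:
    out = []
    pos = 0
    for seg in segments:
        end = pos + len(seg.residues)
        if seg.role == "sp":
            out.append(DomainAnnotation(leaf, "SP", pos, end))
        elif seg.role == "fn3":
            out.append(DomainAnnotation(leaf, "FN3", pos, end,
                                        ordinal=seg.meta["ordinal"]))
        elif seg.role == "tm":
            out.append(DomainAnnotation(leaf, "TM", pos, end))
        elif seg.role == "ptp":
            out.append(DomainAnnotation(leaf, "PTP", pos, end))
        pos = end
    return out


def _gene_model_for(leaf: str, segments: list[_Segment], plan: GroupPlan,
                    strand: str) -> tuple[GeneModel, dict[int, str]]:
    """Place planted introns around/inside each FN3 repeat and build the
    exon table.  Returns the model and the truth code per FN3 ordinal."""
    protein_len = sum(len(s.residues) for s in segments)
    introns: list[int] = []   # cumulative CDS positions (nt)
    truth: dict[int, str] = {}
    pos = 0
    for seg in segments:
        start, end = pos, pos + len(seg.residues)
        pos = end
        if seg.role != "fn3":
            continue
        ordinal = seg.meta["ordinal"]
        code = plan.introns.get(ordinal, "1:1")
        up, internal, down = _parse_intron_plan(code)
        parts = []
        if up is not None:
            introns.append(3 * start + up)
            parts.append(str(up))
        L = end - start
        for i, ph in enumerate(internal):
            p = start + (i + 1) * L // (len(internal) + 1)
            introns.append(3 * p + ph)
            parts.append(str(ph))
        if down is not None:
            introns.append(3 * end + down)
            parts.append(str(down))
        truth[ordinal] = ":".join(parts)
    cds_len = 3 * protein_len + 3  # incl. stop
    cuts = sorted(set(introns))
    if any(c <= 0 or c >= cds_len for c in cuts):
        raise ConfigError(f"{leaf}: intron outside CDS")
    bounds = [0] + cuts + [cds_len]
    cds_lengths = [b - a for a, b in zip(bounds, bounds[1:])]
    exons: list[tuple[int, int]] = []
    g = _GENOMIC_OFFSET
    for L in cds_lengths:
        exons.append((g, g + L))
        g += L + _INTRON_LEN
    if strand == "-":
        total = g
        exons = [(total - e, total - s) for s, e in exons]
    gm = GeneModel(protein_id=leaf, exons=exons, strand=strand,
                   cds_lengths=cds_lengths)
    gm.validate_frame(protein_len, stop_included=True)
    return gm, truth


def _cds_for(protein: str) -> str:
    return "".join(_PREFERRED_CODON[a] for a in protein) + "TAA"


# ----------------------------------------------------------- entry point

@dataclass
class SimulatedFamily:
    """All artefacts of one simulated family, with planted truth tables."""

    config: SimConfig
    tree: Tree
    proteins: list[ProteinRecord]
    cds: dict[str, str]
    gene_models: dict[str, GeneModel]
    domains: list[DomainAnnotation]
    truth: pd.DataFrame           # per-protein planted characters
    groups: list[GroupDefinition]

    def ptp_domains(self) -> list[tuple[str, str]]:
        """(label, PTP-domain sequence) pairs, the phylogenetic substrate."""
        by_id = {p.id: p.sequence for p in self.proteins}
        out = []
        for d in self.domains:
            if d.kind == "PTP":
                out.append((d.protein_id, by_id[d.protein_id][d.start:d.end]))
        return out

    def write(self, outdir: str) -> dict[str, str]:
        import os

        from .io import (write_domains, write_fasta, write_gene_models,
                         write_newick_file)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "proteins": os.path.join(outdir, "proteins.fasta"),
            "cds": os.path.join(outdir, "cds.fasta"),
            "genes": os.path.join(outdir, "genes.gff"),
            "domains": os.path.join(outdir, "domains.tsv"),
            "truth": os.path.join(outdir, "truth_characters.tsv"),
            "tree": os.path.join(outdir, "true_tree.nwk"),
            "groups": os.path.join(outdir, "groups.tsv"),
        }
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.cds, paths["cds"])
        write_gene_models(self.gene_models.values(), paths["genes"])
        write_domains(self.domains, paths["domains"])
        self.truth.to_csv(paths["truth"], sep="\t")
        write_newick_file(self.tree, paths["tree"])
        with open(paths["groups"], "w") as fh:
            fh.write("group\tmember\n")
            for g in self.groups:
                for m in sorted(g.members):
                    fh.write(f"{g.name}\t{m}\n")
        return paths


def simulate_family(config: SimConfig | None = None) -> SimulatedFamily:
    """Evolve one family under ``config`` (default: the study conditions)."""
    config = config or default_config()
    tree = config.validate()
    rng = np.random.default_rng(config.seed)

    stems = {frozenset(g.members): g for g in config.groups}
    plan_of_leaf = {m: g for g in config.groups for m in g.members}

    ancestor = _build_ancestor(config.root_plan, config.n_fn3, rng)

    leaf_segments: dict[str, list[_Segment]] = {}

    def walk(node: Clade, segments: list[_Segment]) -> None:
        if node.is_leaf:
            leaf_segments[node.label] = segments
            return
        for child in node.children:
            child_segs = [s.copy() for s in segments]
            _evolve_branch(child_segs, child.length or 0.0,
                           config.subst_rate, config.indel_rate, rng)
            stem_plan = stems.get(frozenset(child.leaf_labels()))
            if stem_plan is not None:
                _apply_plan(child_segs, stem_plan, rng)
            walk(child, child_segs)

    root_segs = [s.copy() for s in ancestor]
    root_plan_hit = stems.get(frozenset(tree.leaf_labels()))
    if root_plan_hit is not None:  # a "group" spanning the whole tree
        _apply_plan(root_segs, root_plan_hit, rng)
    walk(tree.root, root_segs)

    proteins: list[ProteinRecord] = []
    cds: dict[str, str] = {}
    gene_models: dict[str, GeneModel] = {}
    domains: list[DomainAnnotation] = []
    truth_rows = []
    for i, leaf in enumerate(sorted(leaf_segments)):
        segments = leaf_segments[leaf]
        seq = "".join("".join(s.residues) for s in segments)
        species = leaf.split("_")[0]
        proteins.append(ProteinRecord(id=leaf, sequence=seq, species=species,
                                      source="simulated"))
        cds[leaf] = _cds_for(seq)
        plan = plan_of_leaf.get(leaf, config.root_plan)
        strand = "+" if i % 2 == 0 else "-"
        gm, intron_truth = _gene_model_for(leaf, segments, plan, strand)
        gene_models[leaf] = gm
        domains.extend(_domains_for(leaf, segments))
        row: dict[str, object] = {
            "protein_id": leaf,
            "group": plan.name,
            "wpd_triplet": plan.wpd,
            "wpd_class": plan.wpd if plan.wpd in ("WPD", "WPE") else "other",
            "yxn_pattern": {"yxn": "YxN", "otherY": "otherY",
                            "none": "none"}[plan.tail],
        }
        for o in range(1, config.n_fn3 + 1):
            row[f"bcloop_{o}"] = plan.bcloop.get(o, "W4G4Y")
            row[f"introns_{o}"] = intron_truth[o]
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows).set_index("protein_id")
    groups = [GroupDefinition(g.name, frozenset(g.members))
              for g in config.groups if len(g.members) >= 1]
    return SimulatedFamily(config=config, tree=tree, proteins=proteins,
                           cds=cds, gene_models=gene_models, domains=domains,
                           truth=truth, groups=groups)


# ------------------------------------------------- additive distances

def additive_distance_matrix(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Exact leaf-to-leaf path-length metric of a tree with branch lengths."""
    parents: dict[int, tuple[Clade | None, float]] = {}

    def walk(node: Clade, parent: Clade | None) -> None:
        if node is not tree.root and node.length is None:
            raise ConfigError("additive_distance_matrix needs branch lengths")
        parents[id(node)] = (parent, node.length or 0.0)
        for c in node.children:
            walk(c, node)

    walk(tree.root, None)
    leaves = [n for n in tree.postorder() if n.is_leaf]
    labels = sorted(n.label for n in leaves)
    by_label = {n.label: n for n in leaves}

    def path_to_root(node: Clade) -> dict[int, float]:
        out = {}
        d = 0.0
        cur: Clade | None = node
        while cur is not None:
            out[id(cur)] = d
            parent, length = parents[id(cur)]
            d += length
            cur = parent
        return out

    cache = {l: path_to_root(by_label[l]) for l in labels}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            pa, pb = cache[a], cache[b]
            # distance via the deepest common ancestor on the root path
            best = min(pa[k] + pb[k] for k in pa if k in pb)
            D[i, j] = D[j, i] = best
    return labels, D
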