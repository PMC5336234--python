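"""End-to-end pipeline orchestration.

One YAML config drives: simulate (or load user inputs) → structural
characters → PTP-domain similarity → gap-cost sweep + elision → parsimony
search + bootstrap → monophyly table → character-annotated tree → synteny
(if neighborhood inputs are given).  A single seed fans out to per-stage
seeds by stable hashing of the stage name, so stages are individually
reproducible; a manifest records the seed, per-stage seeds and the SHA-256
of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import pandas as pd
import yaml

from . import __version__
from .annot import character_table
from .errors import ConfigError, RptpError
from .io import (read_domains, read_fasta, read_gene_models,
                 write_newick_file, write_similarity)
from .msa import GapCostSweep, elide, sweep_align, write_partitions
from .phylo import (CharacterMatrix, GroupDefinition, bootstrap,
                    is_monophyletic, search_parsimony)
from .charmap import annotate_tree
from .records import ProteinRecord
from .similarity import DEFAULT_THRESHOLD, similarity_matrix
from .simulate import GroupPlan, SimConfig, default_config, simulate_family
from .synteny import compare_neighborhoods, load_neighborhood_tsv

log = logging.getLogger("rptp")


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _sim_config_from_dict(d: dict, seed: int) -> SimConfig:
    base = default_config(seed)
    if not d:
        return base
    groups = [GroupPlan(name=g["name"], members=tuple(g["members"]),
                        bcloop={int(k): v for k, v in g.get("bcloop", {}).items()},
                        wpd=g.get("wpd", "WPD"), tail=g.get("tail", "yxn"),
                        introns={int(k): v for k, v in g.get("introns", {}).items()},
                        juxtamembrane=g.get("juxtamembrane", False))
              for g in d["groups"]] if "groups" in d else base.groups
    return SimConfig(tree=d.get("tree", base.tree), groups=groups,
                     root_plan=base.root_plan,
                     n_fn3=d.get("n_fn3", base.n_fn3),
                     subst_rate=d.get("subst_rate", base.subst_rate),
                     indel_rate=d.get("indel_rate", base.indel_rate),
                     seed=seed)


def run_pipeline(config: dict | str, outdir: str) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``manifest.json`` in ``outdir``).  Any stage failure raises with the
    stage name."""
    if isinstance(config, str):
        config = load_config(config)
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 42))
    manifest: dict = {"version": __version__, "seed": seed, "stages": {},
                      "outputs": {}}
    stage = "setup"
    try:
        # ---------------------------------------------------- inputs
        stage = "inputs"
        if "inputs" in config:
            inp = config["inputs"]
            proteins = read_fasta(inp["proteins"])
            domains = read_domains(inp["domains"])
            gene_models = (read_gene_models(inp["genes"])
                           if "genes" in inp else {})
            groups = []
            if "groups" in inp:
                gdf = pd.read_csv(inp["groups"], sep="\t")
                for name, sub in gdf.groupby("group"):
                    groups.append(GroupDefinition(str(name),
                                                  frozenset(sub["member"])))
            truth = None
        else:
            stage = "simulate"
            sseed = stage_seed(seed, "simulate")
            manifest["stages"]["simulate"] = {"seed": sseed}
            sim_cfg = _sim_config_from_dict(config.get("simulate", {}), sseed)
            fam = simulate_family(sim_cfg)
            paths = fam.write(os.path.join(outdir, "family"))
            manifest["outputs"].update(paths)
            proteins, domains = fam.proteins, fam.domains
            gene_models, groups, truth = fam.gene_models, fam.groups, fam.truth

        by_id = {p.id: p.sequence for p in proteins}
        ptp_domains = [(d.protein_id, by_id[d.protein_id][d.start:d.end])
                       for d in domains if d.kind == "PTP"]
        if not ptp_domains:
            raise ConfigError("no PTP domains in input")

        # ------------------------------------------------- characters
        stage = "characters"
        chars = character_table(proteins, domains, gene_models or None)
        chars_path = os.path.join(outdir, "characters.tsv")
        chars.to_csv(chars_path, sep="\t")
        manifest["outputs"]["characters"] = chars_path
        if truth is not None:
            shared = [c for c in chars.columns if c in truth.columns]
            agree = (chars[shared].astype(str)
                     == truth.loc[chars.index, shared].astype(str))
            manifest["stages"]["characters"] = {
                "planted_recovery": float(agree.values.mean())}

        # ------------------------------------------------- similarity
        stage = "similarity"
        sim = similarity_matrix(ptp_domains)
        sim_prefix = os.path.join(outdir, "similarity")
        threshold = float(config.get("similarity", {}).get(
            "threshold", DEFAULT_THRESHOLD))
        write_similarity(sim, sim_prefix, threshold)
        for suffix in (".evalues.tsv", ".scores.tsv", ".below_threshold.tsv"):
            manifest["outputs"][f"similarity{suffix}"] = sim_prefix + suffix

        # ------------------------------------------------ msa + elide
        stage = "msa"
        sweep_cfg = config.get("msa", {})
        sweep = GapCostSweep(tuple(sweep_cfg.get("costs", (1, 2, 4, 6, 8, 16))))
        seqs = [ProteinRecord(l, s) for l, s in ptp_domains]
        alignments = sweep_align(seqs, sweep)
        elided = elide(alignments)
        from .io import write_fasta
        elided_path = os.path.join(outdir, "elided.fasta")
        write_fasta(dict(zip(elided.msa.labels, elided.msa.rows)), elided_path)
        parts_path = os.path.join(outdir, "partitions.txt")
        write_partitions(elided, parts_path)
        manifest["outputs"]["elided"] = elided_path
        manifest["outputs"]["partitions"] = parts_path

        # ------------------------------------------------------ phylo
        stage = "phylo"
        pseed = stage_seed(seed, "phylo")
        phylo_cfg = config.get("phylo", {})
        n_starts = int(phylo_cfg.get("n_starts", 10))
        n_boot = int(phylo_cfg.get("bootstrap", 100))
        cm = CharacterMatrix.from_msa(elided.msa)
        best, length = search_parsimony(cm, n_starts=n_starts, seed=pseed)
        best_path = os.path.join(outdir, "best_parsimony.nwk")
        write_newick_file(best, best_path)
        boot_tree = bootstrap(cm, n_boot, seed=stage_seed(seed, "bootstrap"),
                              n_starts=int(phylo_cfg.get("boot_starts", 1)))
        boot_path = os.path.join(outdir, "bootstrap_consensus.nwk")
        write_newick_file(boot_tree, boot_path)
        manifest["outputs"]["best_tree"] = best_path
        manifest["outputs"]["bootstrap_consensus"] = boot_path
        manifest["stages"]["phylo"] = {"seed": pseed,
                                       "parsimony_length": length}

        stage = "monophyly"
        mono_rows = []
        for g in groups:
            if len(g.members) < 2 or not g.members < set(best.leaf_labels()):
                continue
            m_best, size_best = is_monophyletic(best, g)
            m_boot, _ = is_monophyletic(boot_tree, g)
            mono_rows.append((g.name, len(g.members), m_best, m_boot, size_best))
        mono = pd.DataFrame(mono_rows, columns=[
            "group", "n_members", "monophyletic_best",
            "monophyletic_bootstrap", "smallest_containing_clade"])
        mono_path = os.path.join(outdir, "monophyly.tsv")
        mono.to_csv(mono_path, sep="\t", index=False)
        manifest["outputs"]["monophyly"] = mono_path
        manifest["stages"]["monophyly"] = {
            "n_groups": int(len(mono)),
            "n_monophyletic": int(mono["monophyletic_bootstrap"].sum())}

        # ---------------------------------------------------- charmap
        stage = "charmap"
        table, nhx, extra = annotate_tree(best, chars)
        table_path = os.path.join(outdir, "tree_characters.tsv")
        table.to_csv(table_path, sep="\t", index=False)
        nhx_path = os.path.join(outdir, "annotated_tree.nhx")
        with open(nhx_path, "w") as fh:
            fh.write(nhx + "\n")
        manifest["outputs"]["tree_characters"] = table_path
        manifest["outputs"]["annotated_tree"] = nhx_path

        # ---------------------------------------------------- synteny
        if "synteny" in config:
            stage = "synteny"
            syn_cfg = config["synteny"]
            if syn_cfg.get("packaged"):
                from .synteny import ptprb_vs_ciona
                hood, b_genes, b_anchor = ptprb_vs_ciona()
            else:
                hood = load_neighborhood_tsv(syn_cfg["neighborhood"],
                                             syn_cfg["genome"])
                b = pd.read_csv(syn_cfg["b_genes"], sep="\t")
                b_genes = dict(zip(b["gene"], b["chromosome"].astype(str)))
                b_anchor = syn_cfg["b_anchor"]
            rep = compare_neighborhoods(hood, b_genes, b_anchor)
            syn_path = os.path.join(outdir, "synteny.tsv")
            rep.as_frame().to_csv(syn_path, sep="\t", index=False)
            manifest["outputs"]["synteny"] = syn_path
            manifest["stages"]["synteny"] = {
                "conserved": len(rep.conserved), "absent": len(rep.absent),
                "elsewhere": len(rep.elsewhere)}
    except RptpError as exc:
        raise RptpError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["hashes"] = {k: _sha256(v) for k, v in
                          sorted(manifest["outputs"].items())
                          if os.path.isfile(v)}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
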