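#!/usr/bin/env python
"""Structural characters mapped onto the tree.

Computes the per-protein character table (WPD triplet/class, C-terminal
YxN pattern, per-ordinal B-C loop codes and FN3 intron codes), joins it to
the inferred tree, and reconstructs the ancestral WPD state by set-valued
Fitch parsimony.
"""

import argparse

from rptp.annot import character_table
from rptp.charmap import annotate_tree, fitch_ancestral
from rptp.io import (read_domains, read_fasta, read_gene_models,
                     read_newick_file)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--family", default="results/family")
    ap.add_argument("--tree", default="results/phylogeny.best.nwk")
    ap.add_argument("--out", default="results/characters")
    args = ap.parse_args()

    proteins = read_fasta(f"{args.family}/proteins.fasta")
    domains = read_domains(f"{args.family}/domains.tsv")
    genes = read_gene_models(f"{args.family}/genes.gff")
    chars = character_table(proteins, domains, genes)
    chars.to_csv(args.out + ".tsv", sep="\t")

    tree = read_newick_file(args.tree)
    table, nhx, extra = annotate_tree(tree, chars)
    table.to_csv(args.out + ".long.tsv", sep="\t", index=False)
    with open(args.out + ".nhx", "w") as fh:
        fh.write(nhx + "\n")

    wpd = {pid: str(chars.loc[pid, "wpd_class"]) for pid in chars.index}
    root_set, _, changes = fitch_ancestral(tree, wpd)
    print(f"characters for {len(chars)} proteins "
          f"({sum(c.startswith('bcloop') for c in chars.columns)} FN3 ordinals)")
    print(f"WPD-class ancestral state set at the root: {sorted(root_set)} "
          f"({changes} parsimony changes)")
    counts = chars["wpd_class"].value_counts().to_dict()
    print(f"WPD classes: {counts}")
    print(f"YxN patterns: {chars['yxn_pattern'].value_counts().to_dict()}")
    print(f"wrote {args.out}.tsv / .long.tsv / .nhx")


if __name__ == "__main__":
    main()
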