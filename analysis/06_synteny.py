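#!/usr/bin/env python
"""Conserved synteny between the vertebrate PTPRB locus and the Ciona_1
locus: classify each vertebrate neighbor gene as conserved near the Ciona
anchor, present elsewhere in the Ciona genome, or absent from it.
"""

import argparse

from rptp.synteny import compare_neighborhoods, ptprb_vs_ciona


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/synteny.tsv")
    args = ap.parse_args()

    hood, b_genes, b_anchor = ptprb_vs_ciona()
    rep = compare_neighborhoods(hood, b_genes, b_anchor)
    rep.as_frame().to_csv(args.out, sep="\t", index=False)
    print(f"{len(hood.neighbors)} neighbors of {hood.anchor} "
          f"vs {b_anchor} locus:")
    print(f"  conserved near anchor: {', '.join(rep.conserved)}")
    print(f"  elsewhere in genome:   {', '.join(rep.elsewhere)}")
    print(f"  absent from genome:    {', '.join(rep.absent)} "
          f"({len(rep.absent)} genes)")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
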