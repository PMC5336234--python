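#!/usr/bin/env python
"""All-vs-all PTP-domain similarity (the heat-map step).

Local-alignment scores and Karlin-Altschul E-values for every pair of PTP
domains, with the E < 1e-80 classification table.  Reports how well the
low-E cells coincide with the planted group structure.
"""

import argparse

import pandas as pd

from rptp.io import read_domains, read_fasta, write_similarity
from rptp.similarity import DEFAULT_THRESHOLD, similarity_matrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--family", default="results/family")
    ap.add_argument("--out", default="results/similarity")
    ap.add_argument("--threshold", type=float, default=DEFAULT_THRESHOLD)
    args = ap.parse_args()

    proteins = {p.id: p for p in read_fasta(f"{args.family}/proteins.fasta")}
    domains = [d for d in read_domains(f"{args.family}/domains.tsv")
               if d.kind == "PTP"]
    pairs = [(d.protein_id,
              proteins[d.protein_id].sequence[d.start:d.end])
             for d in domains]
    sim = similarity_matrix(pairs)
    write_similarity(sim, args.out, args.threshold)

    groups = pd.read_csv(f"{args.family}/groups.tsv", sep="\t")
    group_of = dict(zip(groups["member"], groups["group"]))
    below = sim.classify(args.threshold)
    same = within = 0
    for i, a in enumerate(sim.labels):
        for j, b in enumerate(sim.labels):
            if i < j and group_of.get(a) == group_of.get(b):
                within += 1
                same += bool(below[i, j])
    print(f"{len(pairs)} PTP domains; {int(below.sum())} cells below "
          f"E={args.threshold:g}")
    print(f"within-group pairs below threshold: {same}/{within}")
    print(f"wrote {args.out}.evalues.tsv / .scores.tsv / .below_threshold.tsv")


if __name__ == "__main__":
    main()
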