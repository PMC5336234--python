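"""All-vs-all PTP-domain similarity: local alignment scores and E-values.

The search-engine step of the original comparison (blastp against taxon
restricted databases) is replaced by exact Smith–Waterman with BLOSUM62 and
affine gaps 11/1, with Karlin–Altschul E-values ``E = K * m * n * exp(-λS)``
using the standard gapped constants for that scoring system (K = 0.041,
λ = 0.267).  E-values here are comparable within one run — the heat map and
the below-threshold classification use them ordinally — and are not expected
to match a database search bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import local_affine
from .errors import AlignmentError, ValidationError
from .records import SimilarityMatrix

#: Classification threshold used for the shaded cells of the similarity table.
DEFAULT_THRESHOLD = 1e-80


@dataclass(frozen=True)
class EvalueParams:
    """Karlin–Altschul constants and alignment scoring parameters.

    K and lam are the gapped constants for BLOSUM62 with gap open 11 and
    extend 1 (the blastp defaults this pipeline stands in for).
    """

    K: float = 0.041
    lam: float = 0.267
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValidationError("K and lambda must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap penalties must be positive")


def local_align(a: str, b: str, params: EvalueParams = EvalueParams()
                ) -> tuple[float, tuple[str, str]]:
    """Maximum-scoring local alignment of two protein sequences.

    Returns the raw Smith–Waterman score and the aligned pair; degapping
    the pair yields substrings of ``a`` and ``b``.
    """
    if not a or not b:
        raise AlignmentError("local_align requires non-empty sequences")
    score, ra, rb = local_affine(a, b, params.matrix,
                                 params.gap_open, params.gap_extend)
    return score, (ra, rb)


def evalue(score: float, m: int, n: int,
           params: EvalueParams = EvalueParams()) -> float:
    """Karlin–Altschul expectation for a raw score over an m x n search space."""
    if score < 0:
        raise ValidationError("evalue requires a non-negative score")
    return params.K * m * n * math.exp(-params.lam * score)


def similarity_matrix(domains: list[tuple[str, str]],
                      params: EvalueParams = EvalueParams()
                      ) -> SimilarityMatrix:
    """All-vs-all similarity of labelled PTP-domain sequences.

    Scores are symmetric, so each unordered pair is aligned once.  The
    diagonal holds the self-hit, which must be the row minimum E-value.
    """
    if len(domains) < 2:
        raise ValidationError("similarity_matrix needs at least 2 domains")
    labels = [l for l, _ in domains]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate domain labels")
    seqs = [s for _, s in domains]
    n = len(seqs)
    scores = np.zeros((n, n))
    evals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s, _ = local_align(seqs[i], seqs[j], params)
            scores[i, j] = scores[j, i] = s
            e = evalue(s, len(seqs[i]), len(seqs[j]), params)
            evals[i, j] = evals[j, i] = e
    for i in range(n):
        if evals[i, i] > evals[i].min() + 1e-300:
            raise ValidationError(
                f"self-hit of {labels[i]!r} is not the row-minimum E-value; "
                "input domains are probably degenerate"
            )
    return SimilarityMatrix(labels=labels, evalues=evals, scores=scores)
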