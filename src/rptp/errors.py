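"""Exception hierarchy shared across the package."""


class RptpError(Exception):
    """Base class for all package errors."""


class FastaParseError(RptpError):
    """Malformed FASTA input (duplicate ids, illegal residues, empty file)."""


class NewickParseError(RptpError):
    """Malformed Newick input."""


class GeneModelError(RptpError):
    """Gene model fails a structural invariant (ordering, frame, length)."""


class ValidationError(RptpError):
    """A domain-type invariant is violated."""


class ConfigError(RptpError):
    """A simulation or pipeline configuration is infeasible or malformed."""


class AlignmentError(RptpError):
    """Sequences cannot be aligned or fail a consistency check."""
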