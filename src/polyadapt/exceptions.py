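"""Exception hierarchy for polyadapt."""


class PolyadaptError(Exception):
    """Base class for all polyadapt errors."""


class ParameterError(PolyadaptError, ValueError):
    """An argument is outside its valid domain."""


class DegenerateInputError(PolyadaptError, ValueError):
    """Input data carry no usable signal (e.g. all SNPs monomorphic, VA = 0)."""


class DegenerateAxisError(DegenerateInputError):
    """The geographic axis lies in the null space of the co-ancestry matrix."""


class AlignmentError(PolyadaptError, ValueError):
    """Two tables could not be reconciled SNP-by-SNP (ids or alleles disagree)."""


class FormatError(PolyadaptError, ValueError):
    """A file does not conform to the expected layout."""


class UndefinedStatisticError(PolyadaptError, ValueError):
    """A statistic is undefined on this input (e.g. correlation of a constant)."""
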