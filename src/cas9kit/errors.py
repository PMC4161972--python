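"""Exception hierarchy shared across the toolkit."""


class Cas9KitError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(Cas9KitError, ValueError):
    """A sequence contains characters outside the permitted alphabet."""


class CoordinateError(Cas9KitError, ValueError):
    """A position or interval falls outside its contig."""


class ParameterError(Cas9KitError, ValueError):
    """An argument value is out of its valid range."""


class InputError(Cas9KitError, ValueError):
    """Structurally invalid input data (empty genome, unsorted times, ...)."""


class ParseError(Cas9KitError, ValueError):
    """A file could not be parsed."""


class ConsistencyError(Cas9KitError, ValueError):
    """Cross-file consistency violated (e.g. VCF contig absent from genome)."""


class ReferenceMismatchError(Cas9KitError, ValueError):
    """A donor arm or stated reference base disagrees with the genome."""


class GenerationError(Cas9KitError, ValueError):
    """A synthetic dataset specification is infeasible."""


class UndefinedStatisticError(Cas9KitError, ValueError):
    """A statistic is undefined for the given input (e.g. zero denominator)."""
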