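"""Exception hierarchy.

Configuration problems (bad pools, bad thresholds, missing files) and data
problems (bad sequences, unparseable structures) are kept distinct so the CLI
can map them to different exit codes.
"""


class AbhumanizeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AbhumanizeError):
    """Invalid configuration: empty pool slot, bad threshold, missing file."""


class SchemaError(ConfigurationError):
    """An input table/FASTA pair violates its declared schema."""


class InputError(AbhumanizeError):
    """Invalid user data: bad alphabet, out-of-range length, empty input."""


class AnnotationError(AbhumanizeError):
    """A sequence could not be numbered or segmented under the scheme."""


class PartialChainError(AnnotationError):
    """Chain truncated before FR4; carries the list of missing regions."""

    def __init__(self, message: str, missing: list[str]):
        super().__init__(message)
        self.missing = list(missing)


class GraftingError(AbhumanizeError):
    """A germline segment cannot be grafted into its slot."""


class ConsistencyError(AbhumanizeError):
    """A back-mutation spec disagrees with the design or parent sequence."""


class EnumerationError(AbhumanizeError):
    """Design enumeration received an empty variant list."""


class SegmentLookupError(AbhumanizeError):
    """A germline name was not found in the pool."""


class SamplingError(AbhumanizeError):
    """Library sampling request cannot be satisfied."""


class FormatError(InputError):
    """A structure or table file could not be parsed."""


class ComparisonError(AbhumanizeError):
    """Structure models cannot be compared (e.g. disjoint numbering)."""


class MappingError(AbhumanizeError):
    """Region maps are inconsistent with structure residue numbering."""


class ConstraintError(AbhumanizeError):
    """A requested synthetic geometry is unsatisfiable."""
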