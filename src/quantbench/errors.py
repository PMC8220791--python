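"""Exception hierarchy for quantbench.

All quantbench errors derive from :class:`QuantBenchError` so callers can
catch the whole family; the subclasses mirror the distinct failure modes of
the pipeline stages (file format, cross-sample consistency, degenerate
numerics).
"""


class QuantBenchError(ValueError):
    """Base class for all quantbench errors."""


class FormatError(QuantBenchError):
    """A file does not conform to the expected format (e.g. missing column)."""


class ParseError(QuantBenchError):
    """A cell could not be parsed as the expected type."""


class ConsistencyError(QuantBenchError):
    """Inputs that must agree (gene sets, sample sets) do not."""


class DegenerateSampleError(QuantBenchError):
    """A sample is unusable for the requested computation (all-zero counts,
    zero variance)."""


class InvalidLengthError(QuantBenchError):
    """A gene has positive counts but zero effective length."""


class NoReferenceGeneError(QuantBenchError):
    """Median-of-ratios normalization found no gene positive in all samples."""


class TrimExhaustedError(QuantBenchError):
    """TMM trimming removed every usable gene; smaller trim fractions needed."""


class UndefinedICCError(QuantBenchError):
    """ICC is undefined because all values in the matrix are identical."""


class ConfigError(QuantBenchError):
    """A configuration object is internally inconsistent."""
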