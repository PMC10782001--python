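"""Exception hierarchy for idrbench.

All errors raised by the package derive from :class:`IdrBenchError`, so
callers can catch one type at a pipeline boundary.
"""


class IdrBenchError(Exception):
    """Base class for all idrbench errors."""


class FormatError(IdrBenchError):
    """A file or record violates its documented dialect."""


class DomainError(IdrBenchError):
    """A value lies outside its documented domain (e.g. pLDDT > 100)."""


class ParameterError(IdrBenchError):
    """An operation parameter is invalid (e.g. even smoothing window)."""


class UndefinedMetricError(IdrBenchError):
    """A metric is undefined on the given input (e.g. AUC with one class).

    Callers are expected to exclude the offending protein or subset rather
    than coerce a value.
    """
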