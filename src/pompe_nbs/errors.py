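"""Exception hierarchy for the screening pipeline.

All pipeline errors derive from :class:`PompeNBSError` so callers can catch
one base class; subclasses also derive from the closest stdlib category
(``ValueError`` for bad values, ``KeyError`` never — absence of a KB entry is
a value, not an error).
"""


class PompeNBSError(Exception):
    """Base class for all errors raised by pompe_nbs."""


class VariantParseError(PompeNBSError, ValueError):
    """A variant token could not be parsed (empty or unintelligible)."""


class MalformedGenotypeError(PompeNBSError, ValueError):
    """A genotype string carries more than two primary (allele-bearing) segments."""


class UnresolvedGenotypeError(PompeNBSError, ValueError):
    """A primary allele has classification ``unknown``; KB curation is required
    before a diagnosis may be assigned (never guess silently)."""


class DomainError(PompeNBSError, ValueError):
    """A numeric input is outside its physical/mathematical domain."""


class MissingDataError(PompeNBSError, ValueError):
    """A record lacks the data required for the requested pipeline stage."""


class EmptyGroupError(PompeNBSError, ValueError):
    """A summary or test was requested on a group with no non-missing values."""


class FixtureIntegrityError(PompeNBSError, RuntimeError):
    """A packaged fixture file does not match its pinned checksum."""


class FormatError(PompeNBSError, ValueError):
    """An input table is structurally unreadable (e.g. missing id column)."""


class ConsistencyError(PompeNBSError, ValueError):
    """Aggregate inputs contradict each other (e.g. positives > screened)."""
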