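"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`DmpEnrichError`
so callers (and the CLI) can catch one type.
"""


class DmpEnrichError(Exception):
    """Base class for all package errors."""


class BedParseError(DmpEnrichError):
    """Malformed BED record (non-integer coordinates, end <= start, missing chr prefix)."""


class ManifestError(DmpEnrichError):
    """Probe manifest cannot be read or violates its invariants."""


class AnnotationError(DmpEnrichError):
    """Probe annotation token outside the closed vocabulary."""


class StoreError(DmpEnrichError):
    """Overlap store unreadable, version-mismatched, truncated, or inconsistent."""


class InputFormatError(DmpEnrichError):
    """Probe-set input unresolvable: mixed formats, undetectable format, or zero usable probes."""


class ProbeSetSizeError(DmpEnrichError):
    """Test-set size outside the configured bounds in strict mode."""


class BackgroundPoolError(DmpEnrichError):
    """A background bin's pool is too small for the matched draw."""


class FixtureError(DmpEnrichError):
    """Synthetic-fixture specification infeasible."""
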