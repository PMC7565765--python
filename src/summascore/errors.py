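"""Exception hierarchy.

Configuration problems (bad language codes, unusable reference bundles,
missing analyzer backends) are distinguished from data-validation problems
(malformed batch rows, out-of-range scores) because the command-line
interface maps them to different exit codes.
"""


class SummascoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SummascoreError):
    """A resource, reference bundle or option is unusable as configured."""


class LexiconError(ConfigurationError):
    """A lexicon file violates its format or its internal invariants."""


class ValidationError(SummascoreError):
    """Input data (batch rows, rating pairs) failed validation.

    ``errors`` carries one message per offending row so callers can report
    every problem in a single pass.
    """

    def __init__(self, message: str, errors: list[str] | None = None):
        super().__init__(message)
        self.errors = errors or [message]


class FixtureError(SummascoreError):
    """A planted fixture parameter is unachievable with the given resources."""
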