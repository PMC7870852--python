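"""Exception hierarchy for nirsosc.

All errors raised on bad user input derive from :class:`NirsoscError` so
callers can catch one base class; configuration problems and data-format
problems are distinguished because pipelines typically want to abort on the
former and report file/row context for the latter.
"""


class NirsoscError(Exception):
    """Base class for all nirsosc errors."""


class ConfigurationError(NirsoscError, ValueError):
    """An analysis parameter violates its documented constraints."""


class DataFormatError(NirsoscError, ValueError):
    """An input file or in-memory series violates the expected schema."""


class ChannelError(NirsoscError, KeyError):
    """A required named channel (or chromophore column) is absent or mismatched."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return super(KeyError, self).__str__()


class ConditioningError(NirsoscError, ValueError):
    """A least-squares design matrix is rank deficient or too ill-conditioned."""
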