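"""Exception hierarchy shared across the pipeline.

All user-input problems derive from :class:`InputError` so the CLI can map
them to exit code 2 uniformly.
"""


class GbgcScanError(Exception):
    """Base class for all package errors."""


class InputError(GbgcScanError, ValueError):
    """Invalid user-supplied data (bad table, bad parameter, missing file)."""


class FormatError(InputError):
    """A file violates its format contract (e.g. ragged FASTA alignment)."""


class TooShortError(InputError):
    """An alignment is shorter than the requested trim length."""


class FrameError(InputError):
    """A coding sequence length is not a multiple of three."""


class NotComputableError(GbgcScanError):
    """A test statistic is undefined on the given alignment.

    This is a *signal*, not a failure: families raising it are classified
    ``unclassified`` downstream.
    """
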