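"""Typed exceptions raised by the pipeline.

All pipeline failures derive from :class:`LcrQcError` so callers (and the
command-line layer) can distinguish expected data problems from bugs.
"""


class LcrQcError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LcrQcError):
    """An input file violates the expected dialect (bad row, bad header...)."""


class ValidationError(LcrQcError):
    """Inputs are well-formed but mutually inconsistent (e.g. universe
    mismatch between samples, degenerate batch)."""
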