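"""Exception hierarchy.

ContractError marks violations of an operation's input contract (bad shapes,
degenerate designs, mismatched feature spaces); NumericalError marks failures
that arise during otherwise-valid computation. The CLI maps these to distinct
exit codes.
"""


class FsvaError(Exception):
    """Base class for all package errors."""


class ContractError(FsvaError, ValueError):
    """A data or parameter contract was violated."""


class NumericalError(FsvaError, RuntimeError):
    """A numerical procedure failed (singular system, non-convergence)."""
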