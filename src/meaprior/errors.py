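"""Exception hierarchy shared across the pipeline.

Input errors (bad files, inconsistent dimensions) map to CLI exit code 2;
contract violations (arguments outside an operation's stated domain) map
to exit code 3.
"""


class MeaPriorError(Exception):
    """Base class for all package errors."""


class InputError(MeaPriorError):
    """Missing or malformed input data (file, dimension, format)."""


class DimensionError(InputError):
    """Image or array dimensions inconsistent with the electrode grid."""


class ContractError(MeaPriorError):
    """An argument violates an operation's stated precondition."""
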