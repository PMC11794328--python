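"""Exception hierarchy.

``ValueError`` is used for plain argument-domain violations (bad k, negative
threshold, p outside (0,1]); the classes below mark structural problems.
"""


class DrugeffError(Exception):
    """Base class for drugeff-specific errors."""


class ContractError(DrugeffError):
    """Inputs violate an inter-module contract (mismatched namespaces,
    empty required layers, incompatible roles)."""


class InputFormatError(DrugeffError):
    """A file does not conform to its declared schema (missing columns,
    malformed IDs, bad rows). CLI maps this to exit code 2."""
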