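"""Exception types shared across the package."""


class ChardispError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ChardispError, ValueError):
    """Malformed tree or table input."""


class ValidationError(ChardispError, ValueError):
    """Inputs that parse but violate a contract (unknown labels, bad states...)."""


class NumericalError(ChardispError, ArithmeticError):
    """Irrecoverable numerical failure (not mere optimizer non-convergence)."""
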