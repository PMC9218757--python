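"""Exception hierarchy shared across the pipeline."""


class RgbdFruitError(Exception):
    """Base class for all package errors."""


class ParameterError(RgbdFruitError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class InputError(RgbdFruitError, ValueError):
    """An input array or value violates a precondition."""


class FormatError(RgbdFruitError, ValueError):
    """A file decoded to something other than the expected layout."""


class DegenerateInputError(InputError):
    """The input is too degenerate to process (e.g. an all-invalid depth map)."""


class InternalConsistencyError(RgbdFruitError, RuntimeError):
    """An invariant that should hold by construction was violated."""
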