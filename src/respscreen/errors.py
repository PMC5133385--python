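"""Exception hierarchy for the screen-analysis pipeline."""


class RespScreenError(Exception):
    """Base class for all errors raised by respscreen."""


class InvalidParameterError(RespScreenError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyPlateError(RespScreenError):
    """Every position on a plate is missing; no statistic can be formed."""


class ParseError(RespScreenError):
    """A table file could not be parsed; the message names the line."""


class BoundsError(RespScreenError):
    """A grid coordinate lies outside the declared plate dimensions."""


class DuplicatePositionError(RespScreenError):
    """Two records claim the same (row, col) grid position."""


class LayoutError(RespScreenError):
    """A library layout is inconsistent (gene at two positions, etc.)."""


class ConsistencyError(RespScreenError):
    """Two inputs that must share a gene universe do not."""


class ConfigError(RespScreenError):
    """A run configuration is invalid (unknown key, bad value)."""
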