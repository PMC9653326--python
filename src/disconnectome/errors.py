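"""Exception hierarchy shared by all pipeline stages."""


class DisconnectomeError(Exception):
    """Base class for all package errors."""


class ParameterError(DisconnectomeError, ValueError):
    """An argument is outside its documented domain."""


class GeometryError(DisconnectomeError, ValueError):
    """Two volumes that must share a grid geometry do not."""


class DegenerateDataError(DisconnectomeError, ValueError):
    """Input data carry no usable signal (all-zero, empty mask, ...)."""


class AlignmentError(DisconnectomeError, ValueError):
    """Region profiles are not aligned on identical region ids."""


class UnderdeterminedError(DisconnectomeError, ValueError):
    """Fewer observations than the regression requires."""


class CollinearityError(DisconnectomeError, ValueError):
    """A regression design is rank-deficient or near-singular."""
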