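"""Exception hierarchy shared across coacerlab."""


class CoacerlabError(Exception):
    """Base class for all coacerlab errors."""


class ParameterError(CoacerlabError, ValueError):
    """A physical or algorithmic parameter is out of its valid range."""


class InputError(CoacerlabError, ValueError):
    """An input dataset violates its contract (shape, labels, ordering)."""


class FitError(CoacerlabError, RuntimeError):
    """A model fit failed or produced an unphysical result."""


class InconsistencyError(CoacerlabError, ValueError):
    """Quantities that must agree (e.g. a mass balance) do not."""


class SchemaError(InputError):
    """A table does not match the expected column schema."""


class ConvergenceError(FitError):
    """An iterative solver did not converge within its iteration cap."""
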