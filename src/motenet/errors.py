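"""Exception types shared across the pipeline."""


class MotenetError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MotenetError):
    """A simulation or pipeline configuration violates its invariants."""


class FormatError(MotenetError):
    """An input file does not match the expected dialect."""


class ConvergenceError(MotenetError):
    """An iterative fit failed to converge within its iteration budget."""


class DegenerateDataError(MotenetError):
    """Data cannot support the requested computation (zero variance,
    singleton groups, all-zero outcomes, ...)."""


class CollinearityError(MotenetError):
    """Predictors are too collinear for a stable joint fit."""


class MissingDataError(MotenetError):
    """An id required by a computation is absent from its inputs."""
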