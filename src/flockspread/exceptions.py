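"""Exception hierarchy shared across the package."""


class FlockspreadError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FlockspreadError):
    """A generator or pipeline configuration field is invalid or infeasible."""


class InputError(FlockspreadError):
    """Input data violates a precondition (mixed labels, out-of-range value...)."""


class StateError(FlockspreadError):
    """A simulation was asked to advance from an impossible state."""


class NetworkFileError(InputError):
    """A network file failed validation.

    Carries the full list of violations; a partially valid network is never
    returned.
    """

    def __init__(self, path, violations):
        self.path = str(path)
        self.violations = list(violations)
        msg = f"{path}: {len(self.violations)} validation error(s):\n" + "\n".join(
            f"  - {v}" for v in self.violations
        )
        super().__init__(msg)
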