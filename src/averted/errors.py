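"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`AvertedError`, so callers (and the CLI) can catch model errors
without swallowing programming mistakes.
"""


class AvertedError(Exception):
    """Base class for all model errors."""


class FieldValidationError(AvertedError, ValueError):
    """An input value violates its documented bounds; names the field."""

    def __init__(self, field: str, value, constraint: str):
        self.field = field
        self.value = value
        super().__init__(f"{field}={value!r} violates constraint: {constraint}")


class UnknownInterventionError(AvertedError, ValueError):
    """A scenario references an intervention absent from the parameter set."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(
            "scenario references unknown intervention(s): " + ", ".join(self.names)
        )


class UndefinedSlopeError(AvertedError, ZeroDivisionError):
    """Linear effectiveness extrapolation from zero observed coverage."""


class DegenerateDistributionError(AvertedError, ValueError):
    """A prevalence redistribution has no mass to redistribute."""


class UnparameterizedPathwayError(AvertedError, ValueError):
    """An indirect pathway was invoked without its required parameter."""


class PackValidationError(AvertedError, ValueError):
    """A parameter pack failed schema validation; carries pointer-style paths."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid parameter pack:\n" + "\n".join(self.problems))
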