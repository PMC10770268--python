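"""Exception hierarchy.

Engine errors deliberately carry enough text to appear verbatim as refusal
reasons in session reports; the controller never lets them escape as partial
state changes.
"""


class SurgflowError(Exception):
    """Base class for all package errors."""


class ModelParseError(SurgflowError):
    """XML could not be parsed; carries the source line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ModelValidationError(SurgflowError):
    """A model violates a structural invariant."""

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = problems or [message]
        if problems:
            message = message + ": " + "; ".join(problems)
        super().__init__(message)


class UnsupportedElementError(ModelValidationError):
    """The XML contains element kinds outside the supported subset."""

    def __init__(self, elements: list[str]):
        self.elements = sorted(set(elements))
        super().__init__(f"unsupported elements: {', '.join(self.elements)}")


class UnsupportedRuleError(ModelValidationError):
    """A CMMN rule expression is not a literal boolean constant."""


class UnknownElementError(SurgflowError):
    """Lookup of a node / plan-item id failed."""


class EngineError(SurgflowError):
    """Base class for runtime refusals of either engine."""


class OutOfOrderError(EngineError):
    """A task was completed that is neither active nor activatable."""


class LateOptionalError(OutOfOrderError):
    """An optional task was attempted after its bypass was already taken."""


class RegressionError(EngineError):
    """An already-completed task was completed again."""


class LifecycleError(EngineError):
    """An illegal CMMN plan-item lifecycle transition."""


class StageIncompleteError(LifecycleError):
    """Manual stage completion attempted with required children incomplete."""


class StageBusyError(LifecycleError):
    """Manual stage completion attempted while a child is still active."""


class CaseIncompleteError(LifecycleError):
    """Case completion attempted with required items incomplete."""


class ClosedCaseError(LifecycleError):
    """Any transition attempted on a closed (immutable) case."""


class ReplayError(SurgflowError):
    """A trace prefix could not be replayed on a fresh instance."""
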