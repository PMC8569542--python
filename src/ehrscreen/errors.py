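"""Exception hierarchy for the screening toolkit."""


class EhrScreenError(Exception):
    """Base class for all toolkit errors."""


class TemplateValidationError(EhrScreenError):
    """Template JSON violates the dialect schema; message names the path."""


class UnsupportedTypeError(TemplateValidationError):
    """A node declares an rm_type outside the supported reference-model set."""


class RegistryCollisionError(EhrScreenError):
    """Two concepts (or a derived concept and a simple one) claim the same key."""


class BindingTypeError(EhrScreenError):
    """StartTime/EndTime bound to a non-temporal template node."""


class ELSyntaxError(EhrScreenError):
    """Expression text failed to parse.

    Carries ``line`` and ``column`` of the offending token.
    """

    def __init__(self, message: str, line: int = 1, column: int = 0):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class UnresolvedReferenceError(EhrScreenError):
    """An identifier matches no concept and no derived concept."""


class AmbiguousReferenceError(EhrScreenError):
    """An identifier matches more than one concept path; lists candidates."""

    def __init__(self, name: str, candidates):
        self.name = name
        self.candidates = list(candidates)
        super().__init__(
            f"ambiguous reference {name!r}: candidates {sorted(self.candidates)}"
        )


class DependencyCycleError(EhrScreenError):
    """Derived-concept definitions form a cycle; names the members."""

    def __init__(self, members):
        self.members = list(members)
        super().__init__(f"cyclic derived-concept definitions: {self.members}")


class ConstraintError(EhrScreenError):
    """Bad constraint template, parameter, or degenerate interval."""


class DegenerateIntervalError(ConstraintError):
    """Point interval (start == end) passed to the temporal classifier."""


class MappingError(EhrScreenError):
    """Template-to-index mapping failure (naming collision, unsupported type)."""


class FlatteningError(EhrScreenError):
    """Entry data does not conform to the template node types; names the path."""


class CompilationError(EhrScreenError):
    """Screening condition cannot be compiled to the query IR."""


class EvaluationError(EhrScreenError):
    """Reference-engine evaluation failure (e.g. unit mismatch)."""


class UnitMismatchError(EvaluationError):
    """Two quantities with different unit strings were compared."""


class ConfigError(EhrScreenError):
    """Invalid generator or run configuration."""
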