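"""Exception and warning types shared across the toolkit."""


class BoronfitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(BoronfitError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class InvalidKeyError(BoronfitError):
    """An atom-type key is malformed (wrong arity, empty or illegal labels)."""


class ParameterGapError(BoronfitError):
    """Enumerated interaction terms could not be resolved in the parameter set."""

    def __init__(self, missing_keys):
        self.missing_keys = list(missing_keys)
        keys = ", ".join("-".join(k) for k in self.missing_keys)
        super().__init__(f"missing force-field parameters for: {keys}")


class AlignmentError(BoronfitError):
    """Structure and energy inputs disagree in length or ordering."""


class DegenerateGeometryError(BoronfitError):
    """Zero-length or collinear bond vectors make an internal coordinate undefined."""


class NonRotatableError(BoronfitError):
    """The requested scan axis lies in a ring, so no rigid rotation exists."""


class SchemaMismatchError(BoronfitError):
    """Reference table and computed report do not share the same torsion labels."""


class EmptyInputError(BoronfitError):
    """An operation that needs at least one element received none."""


class LossyExportWarning(UserWarning):
    """Strict-dialect frcmod export rounded a periodicity beyond recovery."""


class LowCoverageWarning(UserWarning):
    """A fitted torsion's conformer set leaves much of the angular range unsampled."""


class RankDeficiencyWarning(UserWarning):
    """The fit specification is underdetermined at the solution."""


class NonConvergenceWarning(UserWarning):
    """The optimizer stopped without meeting its convergence criterion."""
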