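"""Exception hierarchy for the cooccur package."""


class CooccurError(Exception):
    """Base class for all package errors."""


class ValidationError(CooccurError):
    """A record violates a dataset invariant.

    Carries row-level diagnostics in ``problems`` (list of strings).
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        msg = "; ".join(self.problems[:10])
        if len(self.problems) > 10:
            msg += f" ... ({len(self.problems)} problems total)"
        super().__init__(msg)


class ReferentialIntegrityError(ValidationError):
    """A liana/epiphyte record points at a tree that does not exist."""


class ConfigurationError(CooccurError):
    """Inconsistent generator or pipeline configuration."""


class DegenerateTableError(CooccurError):
    """A contingency table has a zero margin; expected counts undefined."""


class SeparationError(CooccurError):
    """A group contrast is degenerate (e.g. an all-zero group)."""


class DegenerateDesignError(CooccurError):
    """A contrast was requested but only one group level is present."""


class InsufficientPointsError(CooccurError):
    """Too few marked points for a point-pattern statistic."""
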