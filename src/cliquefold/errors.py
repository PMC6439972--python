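"""Exception hierarchy shared across cliquefold."""


class CliquefoldError(Exception):
    """Base class for all cliquefold errors."""


class InputError(CliquefoldError):
    """Malformed or inconsistent user input (files, candidates, coordinates)."""


class ScoringError(CliquefoldError):
    """A candidate cannot be scored (e.g. a non-canonical base pair)."""


class SolverError(CliquefoldError):
    """The search cannot run on this graph (e.g. no interaction candidates)."""


class EvaluationError(CliquefoldError):
    """Prediction/reference mismatch during scoring against a reference."""


class GuardExceeded(CliquefoldError):
    """An exhaustive enumeration would exceed its combination guard bound."""
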