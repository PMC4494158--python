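"""Exception hierarchy for the dark-repression pipeline."""


class DarkrepError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DarkrepError, ValueError):
    """An invalid parameter or an infeasible parameter combination."""


class StructuralError(DarkrepError):
    """The data lack a structural element the operation requires
    (e.g. no light time-0 sample for an experiment, missing contrast)."""


class DegenerateInputError(DarkrepError, ValueError):
    """Numerically degenerate input: zero totals, zero-variance profiles,
    non-positive reference means."""


class InsufficientReplicationError(DarkrepError):
    """Fewer than two replicate experiments where a variance is needed."""


class NoFeasibleParametersError(DarkrepError):
    """No point of the (m, t) grid satisfies the FDR constraint."""


class CoarsePermutationWarning(UserWarning):
    """The permutation space is smaller than the requested number of
    permutations; it is enumerated exhaustively instead."""
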