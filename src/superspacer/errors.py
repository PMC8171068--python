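"""Exception hierarchy for superspacer."""


class SuperspacerError(Exception):
    """Base class for all package errors."""


class RationalizationError(SuperspacerError):
    """No fraction within tolerance under the denominator bound.

    Signals an effectively incommensurate q component: the supercell
    approximation the caller asked for does not exist within the bound.
    """


class NoModulationError(SuperspacerError):
    """Intensity profile shows no satellite structure above the contrast threshold."""


class NoTncsError(SuperspacerError):
    """Patterson section has no non-origin peaks above the threshold."""


class AmbiguousChainMatchError(SuperspacerError):
    """Two candidate chains fall within the match tolerance of one reference chain."""

    def __init__(self, reference: str, candidates: list[str]):
        self.reference = reference
        self.candidates = candidates
        super().__init__(
            f"ambiguous family match: chains {candidates} are all within the match "
            f"tolerance of reference chain {reference!r}; supply an explicit "
            "chain-family map to disambiguate"
        )


class NoResetError(SuperspacerError):
    """Series has no negative cyclic jump, hence no sawtooth reset."""


class ModelBuildError(SuperspacerError):
    """Synthetic model construction failed (placement density, boundary crossing)."""


class FormatError(SuperspacerError):
    """Coordinate or reflection file could not be interpreted."""
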