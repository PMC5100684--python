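"""Exception hierarchy shared across the package."""


class SbemkitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SbemkitError, ValueError):
    """An argument violates a documented precondition."""


class NoSignalError(SbemkitError):
    """An image carries no usable signal (e.g. constant intensity)."""


class FormatError(SbemkitError):
    """A file violates the expected on-disk format."""


class GeometryError(SbemkitError):
    """Degenerate geometry (coplanar hull points, zero-volume region, ...)."""


class DisconnectedGraphError(SbemkitError):
    """The tile pair graph does not connect all tiles."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        super().__init__(
            f"pair graph is disconnected; components: {self.components}"
        )


class FetchError(SbemkitError):
    """A cube could not be retrieved from the backing source."""


class NonConvergenceError(SbemkitError):
    """Consensus iteration hit the round cap with mismatches still open."""

    def __init__(self, open_mismatches, rounds):
        self.open_mismatches = open_mismatches
        self.rounds = rounds
        super().__init__(
            f"{len(open_mismatches)} mismatch point(s) still open "
            f"after {rounds} rounds"
        )
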