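"""Exception types shared across the toolkit."""


class JunctionKitError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(JunctionKitError, ValueError):
    """A caller supplied an argument violating a documented precondition."""


class NoAnchorError(JunctionKitError):
    """No exact seed of the configured length anchors the read to a reference."""


class SimulationInfeasibleError(JunctionKitError):
    """The requested junction cannot be simulated on the given references
    (e.g. no microhomology of the requested length exists in both overhangs)."""


class FixtureIntegrityError(JunctionKitError):
    """The bundled junction-table fixture failed its checksum."""


class ReferenceIOError(JunctionKitError, IOError):
    """A reference file could not be parsed; the message names the file."""
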