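"""Exception hierarchy shared across the package."""


class CarbscanError(Exception):
    """Base class for all package errors."""


class ParseError(CarbscanError):
    """A structure file could not be parsed."""


class FormatError(CarbscanError):
    """Unknown or unsupported file format."""


class PairingError(CarbscanError):
    """Atom pairing for superposition failed (mismatch or duplicates)."""


class DegenerateGeometryError(CarbscanError):
    """Point set is rank-deficient (e.g. collinear) for a rigid fit."""


class SelectionError(CarbscanError):
    """A selection required to be non-empty matched nothing."""


class ParameterizationError(CarbscanError):
    """Atoms without force-field parameters."""

    def __init__(self, offenders: list[str]):
        self.offenders = list(offenders)
        super().__init__(
            "unparameterized atoms: " + ", ".join(self.offenders)
        )


class TopologyError(CarbscanError):
    """Residue or ligand topology missing or inconsistent."""


class MinimizationError(CarbscanError):
    """Geometry relaxation could not start (non-finite energy/gradient)."""


class FixtureSpecError(CarbscanError):
    """Infeasible synthetic-fixture specification."""
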