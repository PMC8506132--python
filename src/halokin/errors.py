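"""Exception hierarchy shared across halokin modules."""


class HalokinError(Exception):
    """Base class for all halokin-specific errors."""


class InvalidParameterError(HalokinError, ValueError):
    """A parameter violates its documented domain (e.g. KM <= 0)."""


class FitConvergenceError(HalokinError, RuntimeError):
    """Nonlinear fit failed or the data cannot identify the parameters."""


class InfeasibleAssayError(HalokinError, ValueError):
    """The requested v2/v1 ratio can never be attained with the given spec."""


class IntegrationError(HalokinError, RuntimeError):
    """Numerical integration produced a non-finite state or failed to converge."""


class PDBFormatError(HalokinError, ValueError):
    """A PDB record could not be parsed; the message names the line."""


class EmptyStructureError(HalokinError, ValueError):
    """No ATOM/HETATM records were found."""


class DegenerateGeometryError(HalokinError, ValueError):
    """Point set is rank-deficient; superposition is not unique."""


class SelectionError(HalokinError, ValueError):
    """An atom selection resolved to zero atoms or references unknown atoms."""


class MissingParameterError(HalokinError, ValueError):
    """Nonbonded parameters are missing for selected atoms (listed in message)."""


class ClashError(HalokinError, ValueError):
    """Two atoms in an energy evaluation are unphysically close (< 0.1 A)."""


class FastaFormatError(HalokinError, ValueError):
    """Input is not valid FASTA."""
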