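"""Exception hierarchy shared across the package."""


class EfcaError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(EfcaError):
    """Malformed FASTA input (bad header, duplicate id, bad residue)."""


class AlignmentError(EfcaError):
    """Inconsistent or malformed multiple alignment."""


class SpanError(EfcaError, ValueError):
    """A 1-based residue span lies outside its parent sequence."""


class TrajectoryFormatError(EfcaError):
    """Malformed multi-model PDB or inconsistent frames."""


class TopologyError(EfcaError):
    """Malformed topology (e.g. residue without heavy atoms, mismatch across replicates)."""


class GeometryError(EfcaError):
    """Degenerate geometry for superposition (too few or collinear atoms)."""


class WindowError(EfcaError, ValueError):
    """Analysis window empty or longer than the trajectory provides."""


class ConfigError(EfcaError, ValueError):
    """Invalid run or generator configuration."""


class SingularityError(EfcaError):
    """Potential evaluated at (or too close to) a point charge."""


class PipelineError(EfcaError):
    """A pipeline stage failed; the message names the stage and input."""
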