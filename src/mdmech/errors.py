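"""Exception hierarchy.

Errors are grouped by stage so the CLI can map them onto exit codes:
validation problems (bad config/spec) vs. data problems (malformed or
inconsistent input files) vs. internal consistency failures.
"""


class MDMechError(Exception):
    """Base class for all package errors."""


class ValidationError(MDMechError):
    """A configuration, selection spec or argument is invalid."""


class FormatError(MDMechError):
    """An input file does not conform to its declared format."""


class IntegrityError(MDMechError):
    """A file parses but its content is internally inconsistent
    (duplicate atom ids, count mismatches, empty frames)."""


class SelectionError(ValidationError):
    """A group selection rule produced no atoms or is geometrically invalid."""


class ParameterError(MDMechError):
    """A force-field parameter required by the topology cannot be resolved."""


class KinematicsError(MDMechError):
    """Deformation fitting is ill-posed (rank-deficient reference geometry)."""


class ConsistencyError(MDMechError):
    """An internal invariant was violated (e.g. pairwise decomposition
    residual above tolerance)."""
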