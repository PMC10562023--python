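"""Exception hierarchy for vmatqa."""


class VmatQaError(Exception):
    """Base class for all vmatqa errors."""


class FormatError(VmatQaError):
    """A DICOM or archive file is malformed or missing required elements."""


class UnsupportedPlanError(VmatQaError):
    """The plan is valid DICOM but outside the supported class (single-arc, 60-pair MLC)."""


class GeometryError(VmatQaError):
    """A geometric precondition is violated (e.g. isocenter outside the dose grid)."""


class ParameterError(VmatQaError):
    """A parameter value is out of its admissible range."""


class ConfigurationError(VmatQaError):
    """Configured shapes/exclusions are mutually inconsistent."""


class DegenerateInputError(VmatQaError):
    """Input is degenerate for the requested computation (e.g. empty gamma domain)."""


class ConstructionError(VmatQaError):
    """A network cannot be built for the requested input shapes."""


class TrainingDivergedError(VmatQaError):
    """Training produced a non-finite loss."""
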