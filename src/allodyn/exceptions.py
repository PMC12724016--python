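"""Exception hierarchy shared by all analysis stages."""


class AllodynError(Exception):
    """Base class for every error raised by this package."""


class FormatError(AllodynError):
    """A structure/trajectory/parameter file could not be parsed."""


class EmptyInputError(AllodynError):
    """A file or selection yielded no atoms/frames."""


class AlignmentError(AllodynError):
    """Atom counts or residue lists of two objects do not match."""


class SelectionError(AllodynError):
    """A selection expression is invalid or selects nothing."""


class ParameterError(AllodynError):
    """Per-atom parameters (charge/LJ/radius/mass) missing or invalid."""


class DegenerateFitError(AllodynError):
    """Superposition requested on <3 atoms or a collinear set."""


class InputError(AllodynError):
    """Invalid argument values."""


class GeometryError(AllodynError):
    """Generated or supplied geometry is unphysical (e.g. clashing atoms)."""


class ConfigError(AllodynError):
    """Study configuration invalid; message lists every violation found."""


class NumericalError(AllodynError):
    """A numerical procedure produced an invalid intermediate (e.g. Born radius)."""


class ClashError(AllodynError):
    """Two atoms closer than the hard-sphere floor for energy evaluation."""


class CapabilityError(AllodynError):
    """A stage was requested that the given inputs cannot support."""
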