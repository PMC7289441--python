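"""Exception hierarchy shared across the package."""


class CoprecipError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CoprecipError):
    """A file does not conform to the declared table dialect."""


class ValidationError(CoprecipError):
    """A value violates a data-model invariant."""


class ContractError(CoprecipError):
    """An operation was called with inputs that violate its precondition."""


class ConfigError(CoprecipError):
    """A simulation or pipeline configuration is inconsistent."""


class UndefinedQuantityError(CoprecipError):
    """A quantity (e.g. T3PQ with no peptide areas) is undefined."""


class AbsentBaitError(CoprecipError):
    """The designated bait accession is missing from a ranked list."""


class NoDiscFoundError(CoprecipError):
    """Disc segmentation found no foreground object."""
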