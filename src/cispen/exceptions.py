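"""Package-wide exception types."""


class CispenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CispenError, ValueError):
    """A simulation or analysis configuration is invalid."""


class SimulationError(CispenError, RuntimeError):
    """A simulation could not satisfy its contract (e.g. ascertainment failed)."""


class AlleleMismatchError(CispenError, ValueError):
    """Dosage data and weight table disagree on ref/alt alleles for a variant."""


class UnphasedInputError(CispenError, ValueError):
    """Phased haplotype input was required but the data are unphased."""


class DegenerateDataError(CispenError, ValueError):
    """A statistical test received input on which it is undefined."""
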