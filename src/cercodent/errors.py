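"""Exception hierarchy for cercodent."""


class CercodentError(Exception):
    """Base class for all package errors."""


class SchemaError(CercodentError):
    """Input file is missing required columns or has a malformed header."""


class IntegrityError(CercodentError):
    """Input rows violate a table invariant (duplicates, non-positive metrics)."""


class CycleError(IntegrityError):
    """Pedigree relation graph contains a cycle."""


class FormatError(CercodentError):
    """A tree or file is structurally invalid (e.g. negative branch length)."""


class ConfigError(CercodentError):
    """Run configuration is inconsistent with the requested stages."""


class FitError(CercodentError):
    """Likelihood optimisation failed or produced an inadmissible result."""
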