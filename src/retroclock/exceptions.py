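"""Exception hierarchy shared across the package."""


class RetroclockError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RetroclockError, ValueError):
    """A file does not conform to its declared format (missing columns,
    ragged rows, malformed fields)."""


class ValidationError(RetroclockError, ValueError):
    """Input values violate a domain invariant (beta outside [0, 1],
    negative age, duplicate identifiers, ...)."""


class ConsistencyError(RetroclockError, ValueError):
    """Two artifacts that must agree do not (e.g. a model coefficient file
    and its JSON sidecar list different CpGs)."""


class ChromosomeNamingError(RetroclockError, ValueError):
    """Probe and locus inputs use incompatible chromosome naming
    conventions ('chr1' vs '1') and aliasing was not enabled."""
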