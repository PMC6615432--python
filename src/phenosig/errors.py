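"""Exception hierarchy shared across the pipeline stages."""


class PhenosigError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PhenosigError):
    """A malformed input file (bad cell, missing column, wrong value)."""


class ConsistencyError(PhenosigError):
    """Internally inconsistent data (taxonomy conflicts, duplicate ids,
    abundance/mapping mismatches)."""


class ConfigError(PhenosigError):
    """Invalid configuration (thresholds, design parameters, missing paths)."""


class UnknownTaxonError(PhenosigError, KeyError):
    """A name/rank lookup that does not resolve in the reference collection."""


class UndefinedIndexError(PhenosigError):
    """Phenotype index requested for an unmapped phylotype."""


class DataError(PhenosigError):
    """Numerically invalid data (negative abundance, non-positive copy number)."""


class InsufficientReplicationError(PhenosigError):
    """A group comparison was requested with fewer than two samples per side."""
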