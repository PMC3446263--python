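"""Exception hierarchy for the pipeline.

Errors are split by provenance so the CLI can map them to distinct exit
codes: malformed input files, inconsistent table/manifest pairs, invalid
parameter values, and stage-level failures during computation.
"""


class MetabocorrError(Exception):
    """Base class for all package errors."""


class FormatError(MetabocorrError):
    """A delimited-text input violates the expected layout."""


class ConsistencyError(MetabocorrError):
    """Feature table and sample manifest disagree."""


class ConfigError(MetabocorrError):
    """A parameter or configuration value is out of range or infeasible."""


class StageError(MetabocorrError):
    """A pipeline stage cannot produce output on the given input."""


class TrendFitError(StageError):
    """Too few usable QC points to anchor a loess trend for a feature."""
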