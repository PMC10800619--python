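"""Exception hierarchy for the ehrseq toolkit."""


class EhrseqError(Exception):
    """Base class for all ehrseq errors."""


class ConfigError(EhrseqError):
    """Invalid configuration; the message names the offending field."""


class FormatError(EhrseqError):
    """A file does not match the documented column schema."""


class HierarchyError(EhrseqError):
    """The code hierarchy is not a forest (a cycle was detected)."""


class UnknownCodeError(EhrseqError):
    """An observation code absent from the fitted scaler."""


class UnknownTokenError(EhrseqError):
    """A token absent from the embedding vocabulary."""


class LeakageError(EhrseqError):
    """Data from after the feature cutoff, or from a held-out manifest,
    reached a training path."""


class SamplingError(EhrseqError):
    """A requested sample exceeds the available pool."""


class AlignmentError(EhrseqError):
    """Embedding matrix and sequence vocabulary do not match."""
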