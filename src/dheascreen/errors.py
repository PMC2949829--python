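"""Exception hierarchy for the pipeline."""


class DheascreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DheascreenError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(DheascreenError):
    """Malformed or incomplete input table."""


class ParseError(FormatError):
    """Unreadable file content; the message carries the location."""


class DesignError(DheascreenError):
    """Experimental design does not support the requested computation."""


class ComputationError(DheascreenError):
    """A numeric step cannot be carried out on the given data."""


class EvaluationError(DheascreenError):
    """A gene set cannot be evaluated in the requested context."""
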