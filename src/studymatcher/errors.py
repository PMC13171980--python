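"""Exception hierarchy shared across the package."""


class StudyMatcherError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StudyMatcherError):
    """An input file does not follow the expected dialect."""


class OntologyError(StudyMatcherError):
    """The ontology violates a structural requirement (cycle, dangling edge)."""


class ConfigError(StudyMatcherError):
    """A parameter value is outside its admissible range."""


class AnalysisError(StudyMatcherError):
    """A runtime precondition of an analysis step is violated."""


class ResponseParseError(StudyMatcherError):
    """A text-model response could not be parsed; carries the raw text."""

    def __init__(self, message: str, raw: str = ""):
        super().__init__(message)
        self.raw = raw
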