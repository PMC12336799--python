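"""Exception hierarchy for tg263harm."""


class TG263HarmError(Exception):
    """Base class for all package errors."""


class LexiconError(TG263HarmError):
    """Invalid lexicon file: duplicate names, conflicting synonyms, bad enums."""


class InvalidNameError(TG263HarmError):
    """A structure name failed a basic precondition (e.g. empty string)."""


class IngestError(TG263HarmError):
    """A DICOM or tabular input could not be read as structure names."""


class ConfigurationError(TG263HarmError):
    """A rule set, backend, or run configuration is malformed."""


class TemplateError(TG263HarmError):
    """The prompt template is missing a required placeholder."""


class BackendError(TG263HarmError):
    """A renaming backend failed to produce a response."""
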