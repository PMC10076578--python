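"""Exception hierarchy shared across the pipeline."""


class ArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateUtteranceError(ValueError):
    """An utterance carries no usable speech (e.g. VAD removed every frame)."""


class DataCompletenessError(ValueError):
    """A subject is missing required (task, embedding) entries."""


class NotFittedError(RuntimeError):
    """A model was used before being fitted."""
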