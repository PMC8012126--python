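"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A configuration or operation parameter violates its contract."""


class TrialInvalidError(RuntimeError):
    """A single trial cannot produce a valid result (too few beats,
    degenerate RR series, ...); the trial is dropped, the run continues."""
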