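"""Exception hierarchy for the leafdepo pipeline.

Every error raised by the package derives from :class:`LeafDepoError`, so
callers (and the CLI) can catch pipeline failures without masking genuine
programming errors.
"""


class LeafDepoError(Exception):
    """Base class for all leafdepo errors."""


class SchemaError(LeafDepoError):
    """An input table is missing a required column or has a malformed value."""


class ReferentialError(LeafDepoError):
    """A measurement row references a batch or species that does not exist."""


class ValidationError(LeafDepoError):
    """A value violates a physical or structural invariant (e.g. area <= 0)."""


class MeasurementError(LeafDepoError):
    """A measurement fails quality control beyond the configured tolerance."""


class StageError(LeafDepoError):
    """A pipeline stage failed; carries the stage name and offending record.

    ``stage`` identifies the pipeline step (e.g. ``"gravimetry"``) and
    ``record_id`` the batch/species that triggered the failure, when known.
    """

    def __init__(self, stage: str, message: str, record_id: str | None = None):
        self.stage = stage
        self.record_id = record_id
        where = f"[{stage}" + (f": {record_id}]" if record_id else "]")
        super().__init__(f"{where} {message}")
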