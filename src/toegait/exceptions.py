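"""Exception hierarchy shared across the toegait pipeline.

The CLI maps these onto process exit codes: schema/format problems -> 2,
artifact integrity/version problems -> 3, numeric failures -> 4.
"""


class ToegaitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ToegaitError):
    """An input file does not conform to the documented column schema."""


class FormatError(ToegaitError):
    """An input file is structurally malformed (non-monotone time, missing
    unit declaration, truncated record)."""


class IntegrityError(ToegaitError):
    """A persisted artifact is internally inconsistent (missing channel or
    bin, length mismatch)."""


class VersionError(IntegrityError):
    """A persisted artifact declares an unsupported format version."""


class CollinearityError(ValueError):
    """The regression design matrix is singular; carries the offending
    feature names."""

    def __init__(self, features):
        self.features = list(features)
        super().__init__(
            "design matrix is singular or near-singular; offending features: "
            + ", ".join(self.features)
        )
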