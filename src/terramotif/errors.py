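"""Exception hierarchy for terramotif."""


class TerraMotifError(Exception):
    """Base class for all terramotif errors."""


class SequenceFormatError(TerraMotifError):
    """Unknown or unsupported sequence file format."""


class SequenceParseError(TerraMotifError):
    """Malformed sequence record (e.g. FASTQ length mismatch)."""


class ManifestError(TerraMotifError):
    """Invalid cohort manifest: schema, duplicate ids, labels or paths."""


class AlphabetError(TerraMotifError, ValueError):
    """Sequence contains characters outside {A,C,G,T,N}."""


class AmbiguousKmerError(TerraMotifError, ValueError):
    """A k-mer containing N cannot be assigned a rotation class."""


class DesignError(TerraMotifError, ValueError):
    """Invalid group-comparison design (empty group, bad labels)."""


class StageError(TerraMotifError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
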