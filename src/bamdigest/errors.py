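"""Exception hierarchy for bamdigest.

Every error names the requirement or input that failed, so callers (and the
CLI) can report actionable messages without inspecting tracebacks.
"""


class BamDigestError(Exception):
    """Base class for all bamdigest errors."""


# --- BAM input validation -------------------------------------------------

class MissingFile(BamDigestError):
    """Input file does not exist or is unreadable."""


class NotCoordinateSorted(BamDigestError):
    """BAM header does not declare SO:coordinate."""


class MissingIndex(BamDigestError):
    """No BAI/CSI index found alongside the BAM."""


class TruncatedFile(BamDigestError):
    """BAM stream ended mid-record."""


class NoReadsPass(BamDigestError):
    """Zero alignments pass the inclusion filter."""


# --- genome metadata ------------------------------------------------------

class EmptyFasta(BamDigestError):
    """FASTA contains no sequence data."""


class AnnotationChromMismatch(BamDigestError):
    """Annotation references a sequence absent from the FASTA."""


class CorruptStore(BamDigestError):
    """Genome-metadata store is unreadable or structurally invalid."""


class VersionMismatch(BamDigestError):
    """Genome-metadata store was written by an incompatible schema version."""


class UnknownChromosome(BamDigestError):
    """Requested chromosome is not part of the genome metadata."""


# --- statistics -----------------------------------------------------------

class MalformedCigar(BamDigestError):
    """CIGAR string violates the SAM grammar."""


class MissingQuality(BamDigestError):
    """No sampled record carries base quality scores."""


class MissingSequence(BamDigestError):
    """No sampled record carries a base string."""


class PositionBeyondChromosome(BamDigestError):
    """Alignment extends past the chromosome end: BAM/metadata mismatch."""


class SizeExceedsPopulation(BamDigestError):
    """Requested resample size exceeds the number of passing reads."""


# --- alerts / reporting ---------------------------------------------------

class UnresolvableMetric(BamDigestError):
    """Alert rule names a metric path absent from the results bundle."""


class CorruptResults(BamDigestError):
    """Serialized results bundle is unreadable or structurally invalid."""


class RendererUnavailable(BamDigestError):
    """Requested report backend is not installed."""


# --- simulation -----------------------------------------------------------

class SpecInfeasible(BamDigestError):
    """Simulation parameters cannot produce a valid BAM."""
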