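"""Exception hierarchy.

Every error raised by this package derives from :class:`BlastHitsError`,
so callers (and the CLI) can distinguish data errors from programming errors.
"""


class BlastHitsError(Exception):
    """Base class for all package errors."""


class UnrecognizedFormat(BlastHitsError):
    """Input file is neither BLAST XML nor classic text output."""


class ParseError(BlastHitsError):
    """Malformed BLAST report; carries line or element context in the message."""


class InvalidSpec(BlastHitsError):
    """Synthetic-data specification is empty or inconsistent."""


class FormatError(BlastHitsError):
    """Malformed .bgr file or taxdump file; message carries the line number."""


class VersionError(FormatError):
    """Unknown .bgr format-version header."""


class TaxidConflict(BlastHitsError):
    """The same defline carries two different TAXIDs across merged datasets."""


class MissingName(BlastHitsError):
    """A taxonomy node has no scientific name."""


class UnknownTaxid(BlastHitsError):
    """TAXID not present in the loaded taxonomy tree."""


class UnknownQuery(BlastHitsError):
    """Query name not present in the dataset."""


class UnknownSequence(BlastHitsError):
    """Defline not present in the dataset."""


class UnknownAttribute(BlastHitsError):
    """HSP attribute name not recognised by an axis or statistic."""


class BadEdges(BlastHitsError):
    """Interval-axis bin edges are empty or not strictly increasing."""


class EmptyMatrix(BlastHitsError):
    """Heat-map normalisation requires at least one non-empty cell."""


class NoSuchCell(BlastHitsError):
    """Referenced matrix cell does not exist."""


class RegexError(BlastHitsError):
    """Pattern failed to compile; message carries the offending position."""


class ParentMismatch(BlastHitsError):
    """Set operation on selections from different parent datasets."""


class SourceMissing(BlastHitsError):
    """Original BLAST report needed for alignment extraction is gone."""


class SourceChanged(BlastHitsError):
    """Original BLAST report changed since parsing (checksum mismatch)."""


class NoAlignment(BlastHitsError):
    """The (query, hit) pair has no HSP, or no alignment text is indexed."""
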