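"""Exception hierarchy for phaselink."""


class PhaselinkError(Exception):
    """Base class for all phaselink errors."""


class NewickParseError(PhaselinkError):
    """Malformed Newick input."""


class DuplicateLeafError(PhaselinkError):
    """Two leaves of one tree carry the same (accession, allele) label."""


class SupportRangeError(PhaselinkError):
    """An internal-node support value lies outside [0, 100]."""


class LabelGrammarError(PhaselinkError):
    """Invalid leaf-label grammar configuration or unparseable label."""


class NoOverlapError(PhaselinkError):
    """The two trees share no accession; matching is undefined."""


class MappingError(PhaselinkError):
    """A combination references an accession or allele absent from a tree."""


class CapacityError(PhaselinkError):
    """The global search space exceeds the configured combination cap."""
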