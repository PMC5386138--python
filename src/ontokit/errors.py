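"""Exception hierarchy shared across the toolkit.

Every data-level failure raises a subclass of :class:`OntokitError`, so the
command-line layer can map them uniformly to a non-zero exit status while
library users can catch specific conditions.
"""

from __future__ import annotations


class OntokitError(Exception):
    """Base class for all toolkit data errors."""


class OboParseError(OntokitError):
    """Malformed OBO input (missing id, duplicate id, bad stanza)."""


class CycleError(OntokitError):
    """The parent relation contains a directed cycle.

    Carries ``cycle``: a list of term IDs tracing one offending cycle.
    """

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__(
            "cycle among parent edges: " + " -> ".join(self.cycle + self.cycle[:1])
        )


class DanglingReferenceError(OntokitError):
    """A parent edge points at a term ID not defined in the document.

    Carries ``missing``: sorted list of all undefined target IDs.
    """

    def __init__(self, missing: list[str]):
        self.missing = sorted(missing)
        super().__init__(
            "parent references to undefined terms: " + ", ".join(self.missing)
        )


class UnknownTermError(OntokitError):
    """A queried term ID is not in the index (even via alt_id)."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"unknown term ID: {term_id!r}")


class ObsoleteTermError(OntokitError):
    """A queried term is obsolete and has no replaced_by target."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"term {term_id!r} is obsolete and has no replacement")


class AnnotationParseError(OntokitError):
    """Malformed annotation TSV row."""


class EmptyCorpusError(OntokitError):
    """Information content requested for a corpus with no objects."""


class NoFrequencyError(OntokitError):
    """A term has no annotation frequency, hence no information content."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"term {term_id!r} has no annotation frequency (no IC)")


class EmptySetError(OntokitError):
    """Set-level similarity requested for an empty term set."""


class DegenerateGroupError(OntokitError):
    """Group statistic requested for a group with fewer than two members."""


class DegenerateNullError(OntokitError):
    """Permutation null requested when the group is the whole population."""
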