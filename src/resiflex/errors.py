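"""Exception hierarchy.

All package errors derive from :class:`ResiflexError` so callers can catch
one type at pipeline boundaries; subtypes mirror the failure modes of the
individual stages (file format, topology consistency, degenerate fits,
cohort validation, missing residues).
"""


class ResiflexError(Exception):
    """Base class for all errors raised by resiflex."""


class FormatError(ResiflexError):
    """A file does not conform to its declared format (PDB, fixture, CSV)."""


class TopologyError(ResiflexError):
    """Atoms/residues are inconsistent across frames or with a reference."""


class DegenerateFitError(ResiflexError):
    """A rigid-body fit is underdetermined (< 3 atoms or collinear)."""


class ResidueLookupError(ResiflexError):
    """A requested residue number is absent from the topology/profile."""


class CohortValidationError(ResiflexError):
    """A patient table violates the cohort schema or its invariants.

    ``errors`` holds one human-readable message per offending row/field.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__(
            "cohort validation failed with %d error(s):\n%s"
            % (len(self.errors), "\n".join("  - " + e for e in self.errors))
        )
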