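"""Exception hierarchy for pepotu."""


class PepotuError(Exception):
    """Base class for all pepotu errors."""


class TaxonomyStructureError(PepotuError):
    """The taxonomy violates a structural invariant (missing parent, cycle,
    duplicate taxid, zero or multiple roots, repeated rank on a path)."""


class UnknownTaxonError(PepotuError, KeyError):
    """A taxid was queried that is not present in the tree."""


class UnknownRankError(PepotuError, ValueError):
    """A rank outside the recognised set was requested."""


class MascotFormatError(PepotuError, ValueError):
    """An identification CSV is missing mandatory columns or is unreadable."""


class ProfileError(PepotuError, ValueError):
    """Invalid profile operation (mismatched ranks/tags, degenerate input)."""
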