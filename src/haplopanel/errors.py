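"""Exception hierarchy for the haplopanel pipeline."""


class HaplopanelError(Exception):
    """Base class for all pipeline errors."""


class FormatError(HaplopanelError):
    """A file or cell does not conform to the declared dialect."""


class EmptyResultError(HaplopanelError):
    """A filtering stage removed every SNP or every sample."""

    def __init__(self, stage: str, axis: str):
        self.stage = stage
        self.axis = axis
        super().__init__(f"stage '{stage}' removed all {axis}")


class UndefinedMAFError(HaplopanelError):
    """Minor allele frequency requested on an all-missing call vector."""


class InseparableGroupsError(HaplopanelError):
    """Two haplotype groups share identical allele vectors and cannot be discriminated."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        listing = ", ".join(f"({a}, {b})" for a, b in self.pairs)
        super().__init__(f"inseparable haplotype group pair(s): {listing}")


class ConfigurationError(HaplopanelError):
    """Inputs are mutually inconsistent (e.g. reference groups collide on a tag set)."""


class BoundaryError(HaplopanelError):
    """A flank request runs past a contig edge."""


class ConsistencyError(HaplopanelError):
    """Reference sequence disagrees with a variant's declared ref allele."""
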