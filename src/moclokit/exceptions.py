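"""Exception hierarchy for moclokit."""


class MocloError(Exception):
    """Base class for all moclokit errors."""


class AlphabetError(MocloError):
    """Sequence contains characters outside the strict {A,C,G,T} alphabet."""


class ParseError(MocloError):
    """Malformed FASTA/GenBank input."""


class GenerationError(MocloError):
    """Fixture generation constraints are unsatisfiable."""


class GrammarError(MocloError):
    """A part, fusion site or plan violates the hierarchical assembly grammar."""


class AssemblyFailure(MocloError):
    """No ligation product matches the plan's expected junctions."""

    def __init__(self, message, per_junction=None):
        super().__init__(message)
        self.per_junction = list(per_junction or [])


class AmbiguousAssembly(MocloError):
    """More than one product matches the plan's expected junctions."""


class DigestionError(MocloError):
    """Overlapping cut windows make a digestion unresolvable."""


class DomesticationError(MocloError):
    """A restriction site cannot be removed under the stated constraints."""


class RegistryError(MocloError):
    """Parts-registry file violates its schema or a query is invalid."""
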