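"""Exception hierarchy shared across the pipeline."""


class PepmatchError(Exception):
    """Base class for all pepmatch errors."""


class InvalidSequenceError(PepmatchError):
    """A peptide sequence contains a character outside the 20 canonical residues."""


class InvalidModificationError(PepmatchError):
    """A modification was placed on a residue it does not target."""


class ConfigurationError(PepmatchError):
    """The INI run configuration is missing a key or violates an invariant."""


class SchemaError(PepmatchError):
    """An input CSV lacks a configured column."""


class DataError(PepmatchError):
    """An input file is present but yields no usable rows."""


class DegenerateInputError(PepmatchError):
    """Too little or too uniform data for the requested computation."""


class ContractError(PepmatchError):
    """Caller violated an internal API contract (e.g. mismatched ids)."""
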