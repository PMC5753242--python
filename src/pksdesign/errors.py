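"""Exception hierarchy.

Every error raised by this package derives from :class:`PKSError` so callers
can catch one type at the CLI boundary.
"""


class PKSError(Exception):
    """Base class for all errors raised by pksdesign."""


class SchemaError(PKSError):
    """A cluster/corrections document violates the interchange schema.

    Carries ``path``, a JSON-pointer-like string naming the offending node.
    """

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{path}: {message}")
        self.path = path


class ValidationError(PKSError):
    """A structurally well-formed cluster violates a model invariant."""


class CorrectionError(PKSError):
    """A correction edit addressed a missing module/domain or is malformed."""


class RegistryError(PKSError):
    """Lookup of an unregistered starter/extender/KR type."""


class ChemistryError(PKSError):
    """Base for simulation-stage failures; may carry a module index."""

    def __init__(self, message: str, module_index: int | None = None):
        if module_index is not None:
            message = f"module {module_index}: {message}"
        super().__init__(message)
        self.module_index = module_index


class StateError(ChemistryError):
    """Operation applied to a chain in the wrong tethering state."""


class SubstrateError(ChemistryError):
    """The chain lacks the functional group a domain operates on."""


class ReleaseError(ChemistryError):
    """Product release failed (e.g. cyclization site without a hydroxyl)."""


class InputError(PKSError):
    """Unparsable user input (SMILES, sequence, query)."""


class DecompositionError(PKSError):
    """The retro-biosynthetic parse of a design target failed; the target
    needs manual planning."""
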