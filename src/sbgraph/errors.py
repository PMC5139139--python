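"""Exception hierarchy shared across the package."""


class SbgraphError(Exception):
    """Base class for all package-specific errors."""


class SbgnParseError(SbgraphError):
    """Malformed SBGN-ML input (bad XML, missing map element, ...)."""


class UnsupportedLanguageError(SbgraphError):
    """The map declares a language this package does not handle (e.g. ER)."""


class DanglingReferenceError(SbgraphError):
    """An arc endpoint or compartment reference does not resolve."""


class DuplicateIdError(SbgraphError):
    """Two glyphs (or ports) share an identifier within one map."""


class SerializationError(SbgraphError):
    """A map violating its invariants was handed to the writer."""


class TranslationError(SbgraphError):
    """The SBGN-to-graph translation hit an untranslatable construct."""


class MergeError(SbgraphError):
    """Node-id collision while merging property graphs."""


class GraphLookupError(SbgraphError):
    """A node id passed to a graph operation is not in the graph."""


class ContractError(SbgraphError):
    """A linking procedure received a graph missing required properties."""


class GenerationError(SbgraphError):
    """Synthetic-map generation received infeasible constraints."""


class ExportError(SbgraphError):
    """A graph cannot be serialized in the requested format."""
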