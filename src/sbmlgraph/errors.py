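"""Exception hierarchy for sbmlgraph.

Every error raised deliberately by the package derives from
:class:`SbmlGraphError`, so callers (and the CLI) can distinguish our
failures from programming errors and map them onto exit codes.
"""


class SbmlGraphError(Exception):
    """Base class for all sbmlgraph errors."""


class SchemaParseError(SbmlGraphError):
    """The schema document is not a well-formed Arrows export."""


class SchemaValidationError(SbmlGraphError):
    """The schema document violates a structural invariant (e.g. dangling keys)."""


class SbmlParseError(SbmlGraphError):
    """The SBML input is not well-formed XML."""


class SbmlFormatError(SbmlGraphError):
    """The XML input is well-formed but is not an SBML document."""


class GraphError(SbmlGraphError):
    """A property-graph invariant would be violated (dangling endpoint, key clash)."""


class ConfigurationError(SbmlGraphError):
    """Inconsistent run settings or a schema/extraction mismatch."""


class EmitError(SbmlGraphError):
    """A serialization request cannot be honoured (bad format, bad batch size)."""


class DatabaseError(SbmlGraphError):
    """A live database load failed; the message names the failed batch."""


class DatabaseUnavailableError(DatabaseError):
    """No database driver is installed or no connection could be established."""
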