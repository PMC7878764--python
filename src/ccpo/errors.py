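"""Exception taxonomy shared across the package.

The CLI maps these onto distinct exit codes (schema errors, infeasible
design searches, numerical fit failures and pathway-tree node caps are
different failure modes for a caller).
"""


class CCPOError(Exception):
    """Base class for all package errors."""


class SchemaError(CCPOError):
    """Malformed or inconsistent input (graphs, libraries, designs)."""


class GeometryError(SchemaError):
    """Module geometry incompatible with the edge it was assigned to."""


class InfeasibleDesignError(CCPOError):
    """Requested module multiset cannot populate any requested topology."""


class FitError(CCPOError):
    """A nonlinear fit failed to converge or produced unusable parameters."""


class NodeCapExceeded(CCPOError):
    """Pathway-tree expansion exceeded the configured state cap."""


class MonotonicityError(CCPOError):
    """An effective intra-chain distance increased after a formation event.

    Raised only when pathway expansion runs with auditing enabled; the
    distance metric adds zero-weight links on CC formation, so shortest
    paths must be non-increasing along every pathway.
    """
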