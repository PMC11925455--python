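"""Exception hierarchy shared across the package."""


class RtsbnError(Exception):
    """Base class for all package-specific errors."""


class SchemaViolationError(RtsbnError):
    """A record, file or value does not conform to the variable schema."""


class ConfigurationError(RtsbnError):
    """Invalid configuration: bad constraint sets, tier violations, bad k, ..."""


class InconsistentEvidenceError(RtsbnError):
    """Evidence has exactly zero probability under the network.

    Raised instead of returning an all-zero posterior so that impossible
    scenarios (e.g. a days-to-RTS state contradicting the deterministic
    severity mapping) surface loudly rather than corrupting downstream
    metrics.  Distinct from numerical underflow, which cannot occur for
    the small categorical networks this package targets.
    """
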