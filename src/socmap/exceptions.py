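"""Package exception hierarchy."""


class SocmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SocmapError):
    """Invalid user-supplied configuration (unknown topology, bad counts...)."""


class StructuralError(SocmapError):
    """Inputs violate a structural precondition (disconnected graph, mismatched ids)."""


class StateError(SocmapError):
    """Operation requires state that has not been established (e.g. attributes)."""
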