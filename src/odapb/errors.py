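"""Exception hierarchy for odapb."""


class OdapbError(Exception):
    """Base class for all odapb-specific errors."""


class SingularFitError(OdapbError):
    """Design matrix is rank deficient or a (surrogate) Hessian is singular."""


class NonConvergenceError(OdapbError):
    """The likelihood has no finite maximizer (e.g. no events) or diverges."""


class ProtocolError(OdapbError):
    """A federation-protocol contract was violated (mismatched initial values,
    no usable sites, missing or tampered artifacts)."""


class ValidationError(OdapbError):
    """Input data failed validation (non-binary outcome, missing values, ...)."""


class LinearPredictorOverflowError(OdapbError):
    """A linear predictor exceeded the exp() overflow guard (|eta| > 700).

    Raised instead of silently clipping: a clipped exp corrupts gradients and
    Hessians in ways that are hard to diagnose downstream.
    """
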