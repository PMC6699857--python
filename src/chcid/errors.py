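"""Exception hierarchy for the identification pipeline.

Every error raised on bad scientific input derives from :class:`ChcidError`
so callers (and the pipeline driver, which downgrades per-peak failures to
row status flags) can catch one base class.
"""


class ChcidError(Exception):
    """Base class for all package errors."""


class InsufficientLadderError(ChcidError):
    """Fewer than two usable n-alkane anchors."""


class LadderInversionError(ChcidError):
    """Retention times not strictly increasing with carbon number."""


class NoParentError(ChcidError):
    """No credible molecular-ion candidate in the spectrum."""


class InsufficientEnvelopeError(ChcidError):
    """Fewer than four alkyl-series ions available for the decay fit."""


class DecayFitError(ChcidError):
    """Exponential-envelope fit could not be performed."""


class UnsupportedStructureError(ChcidError):
    """Structure class outside the saturated linear/methyl-branched alkanes."""


class FormulaError(ChcidError):
    """Molecular formula could not be parsed as CxHyOz."""
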