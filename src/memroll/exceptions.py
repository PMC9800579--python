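"""Package-specific error types.

Plain ``ValueError`` is used for ordinary precondition violations (bad
parameter values, empty inputs).  The classes here mark *analysis* failures
that callers may want to catch and inspect: a sigmoid fit that did not
converge, a height histogram that is not bimodal, a particle frame too sparse
for the requested grid, or a synthetic dataset that cannot be generated under
the requested schedule.  Each carries enough context to diagnose the failure
without re-running the analysis.
"""

from __future__ import annotations


class LogisticFitError(RuntimeError):
    """Sigmoid fit failed (flat trace or non-convergent optimisation).

    Attributes
    ----------
    diagnostics : dict
        Trace statistics and, when available, the last parameter estimate.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SegmentationError(RuntimeError):
    """Height histogram is not bimodal; carries the histogram for inspection.

    Attributes
    ----------
    histogram : tuple of (counts, bin_edges)
    """

    def __init__(self, message: str, histogram=None):
        super().__init__(message)
        self.histogram = histogram


class ResolutionError(RuntimeError):
    """Particle frame too sparse for the requested midplane grid."""


class GenerationError(RuntimeError):
    """A synthetic dataset cannot be generated under the requested schedule."""
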