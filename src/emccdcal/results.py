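"""Shared result container for calibration methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalibrationResult"]


@dataclass
class CalibrationResult:
    """Parameter estimates from one calibration run.

    ``estimates`` maps parameter names (e.g. "phi", "g_25x", "E_level2") to
    scalars (single-pixel fits) or H x W arrays (region fits).  ``loglik``
    is the global log-likelihood at the optimum for likelihood methods,
    None for mean-variance fits.  ``meta`` records fixed values (dark-derived
    S0/sigma), scheme names, and summary statistics.
    """

    method: str
    estimates: dict
    loglik: float | np.ndarray | None
    converged: bool | np.ndarray
    se: dict | None = None
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.estimates[key]

    def to_jsonable(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return {
            "method": self.method,
            "estimates": conv(self.estimates),
            "loglik": conv(self.loglik),
            "converged": conv(self.converged),
            "se": conv(self.se),
            "meta": conv(self.meta),
        }
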