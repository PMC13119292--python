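"""Result containers shared by all baseline correctors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IterationRecord:
    """Summary of one corrector iteration."""

    t: int
    residual_norm: float
    weight_min: float
    weight_max: float
    weight_mean: float
    lam_min: float
    lam_max: float


@dataclass
class IterationTrace:
    """Per-iteration history of a corrector run."""

    records: list[IterationRecord] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    def log(self, t: int, residual_norm: float, w: np.ndarray, lam: np.ndarray | float) -> None:
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        self.records.append(
            IterationRecord(
                t=t,
                residual_norm=float(residual_norm),
                weight_min=float(np.min(w)),
                weight_max=float(np.max(w)),
                weight_mean=float(np.mean(w)),
                lam_min=float(np.min(lam)),
                lam_max=float(np.max(lam)),
            )
        )


@dataclass
class CorrectionResult:
    """Output of a baseline corrector.

    ``corrected = raw - baseline`` elementwise before post-processing;
    after non-negativity post-processing (``postprocessed=True``) the
    corrected vector is everywhere >= 0 and ``zeroed`` flags the points
    that were clipped.
    """

    baseline: np.ndarray
    corrected: np.ndarray
    trace: IterationTrace
    lam_final: np.ndarray | float
    postprocessed: bool = False
    zeroed: np.ndarray | None = None

    @property
    def n_iterations(self) -> int:
        return self.trace.n_iterations

    @property
    def converged(self) -> bool:
        return self.trace.converged
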