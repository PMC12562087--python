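"""Thrombin-curve discrepancy: the calibration objective.

The objective is the square root of the sum of squared pointwise distances
(SSSD) between two thrombin-generation curves on a shared 2.5 s sample
grid,

    SSSD = sqrt( Σ_k (TH_ref(t_k) − TH_cand(t_k))² )   [mM],

evaluated over the first 625 s only and with the first 20 saved points
(t = 2.5 s … 50 s) excluded to suppress initialisation transients.  The
t = 0 sample is initialisation, not data; with defaults the retained window
is k = 21…250, i.e. 230 points.  No 1/N normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import Trajectory, thrombin_series

__all__ = [
    "EvaluationWindow",
    "DiscrepancyResult",
    "sssd",
    "averaged_sssd",
    "peak_metrics",
]


@dataclass(frozen=True)
class EvaluationWindow:
    """Sampling/exclusion rules for the discrepancy.

    ``exclude_first`` counts saved points after t = 0: point k sits at
    t = k·sample_interval and is retained iff k > exclude_first and
    t ≤ t_end_eval.
    """

    t_end_eval: float = 625.0
    exclude_first: int = 20
    sample_interval: float = 2.5

    def __post_init__(self) -> None:
        if self.t_end_eval <= self.exclude_first * self.sample_interval:
            raise ValueError("evaluation window is empty: t_end_eval too small")

    def retained_mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask over a sample-time grid selecting the evaluated points."""
        k = np.rint(times / self.sample_interval).astype(int)
        on_grid = np.abs(times - k * self.sample_interval) <= 1e-9 * max(1.0, self.t_end_eval)
        if not np.all(on_grid):
            raise ValueError("trajectory times do not lie on the evaluation sample grid")
        return (k > self.exclude_first) & (times <= self.t_end_eval + 1e-9)


@dataclass(frozen=True)
class DiscrepancyResult:
    """SSSD value with its per-point residuals (reference − candidate, mM)."""

    sssd: float
    n_data: int
    per_point_residuals: np.ndarray

    def __float__(self) -> float:
        return self.sssd


def sssd(reference: Trajectory, candidate: Trajectory,
         window: EvaluationWindow | None = None) -> DiscrepancyResult:
    """Thrombin-curve SSSD between a reference and a candidate trajectory.

    Both trajectories must share the sample grid over the window; grids are
    never silently interpolated.
    """
    window = window or EvaluationWindow()
    t_ref, th_ref = thrombin_series(reference)
    t_cand, th_cand = thrombin_series(candidate)

    mask_ref = window.retained_mask(t_ref)
    mask_cand = window.retained_mask(t_cand)
    tr, tc = t_ref[mask_ref], t_cand[mask_cand]
    if len(tr) != len(tc) or not np.allclose(tr, tc, rtol=0, atol=1e-9):
        raise ValueError("reference and candidate grids differ over the evaluation window")

    residuals = th_ref[mask_ref] - th_cand[mask_cand]
    return DiscrepancyResult(
        sssd=float(np.sqrt(np.sum(residuals**2))),
        n_data=int(len(residuals)),
        per_point_residuals=residuals,
    )


def averaged_sssd(reference_set: Sequence[Trajectory], candidate_set: Sequence[Trajectory],
                  window: EvaluationWindow | None = None) -> float:
    """Arithmetic mean of per-condition SSSD values over paired trajectories.

    Used when calibrating against several tissue-factor conditions at once.
    """
    if len(reference_set) == 0 or len(reference_set) != len(candidate_set):
        raise ValueError("need equal-length, non-empty trajectory sets")
    values = [sssd(r, c, window).sssd for r, c in zip(reference_set, candidate_set)]
    return float(np.mean(values))


def peak_metrics(trajectory: Trajectory) -> tuple[float, float]:
    """Peak thrombin concentration (mM) and the earliest time (s) attaining it."""
    times, th = thrombin_series(trajectory)
    i = int(np.argmax(th))
    return float(th[i]), float(times[i])
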