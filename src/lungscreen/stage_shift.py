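"""Stage-shift mortality model.

Maps a population stage I detection rate to annual lung-cancer deaths
averted, the number needed to screen (NNS), and parity solutions
against comparator screening programs (breast: 10 660 lives/year,
colorectal: 13 650 lives/year).

The response curve is piecewise linear through two calibration anchors:
the current-guideline operating point (16.0% stage I detection, 3 650
lives saved annually) and the realistic age-based projection (30.0%,
26 124 lives). Below the first anchor the curve falls linearly to
(0, 0); above the second it continues along the two-anchor secant. A
single smooth curve cannot pass through all published scenario rows
(their implied slopes differ several-fold), so the two headline anchors
define the default calibration and alternative anchors are accepted via
:class:`StageShiftParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["StageShiftParams", "LivesSaved", "lives_saved", "nns", "parity_rate"]


@dataclass(frozen=True)
class StageShiftParams:
    """Calibration of the stage-shift response.

    ``anchors`` are (stage I rate, lives saved/year) pairs; ``anchor_ci``
    maps each anchor rate to the 95% CI of its lives-saved value, used
    for Monte Carlo uncertainty. ``benefit_scale`` multiplies the whole
    response (0 disables the stage-shift benefit entirely).
    ``case_fatality_by_stage`` records the stage-specific case fatality
    gradient that motivates the model (stage I far below stage IV).
    """

    baseline_stage1_rate: float = 0.16
    baseline_lives_saved: float = 3650.0
    anchors: tuple[tuple[float, float], ...] = ((0.16, 3650.0), (0.30, 26124.0))
    anchor_ci: dict = field(
        default_factory=lambda: {
            0.16: (2800.0, 4500.0),
            0.30: (20000.0, 32248.0),
        }
    )
    comparator_targets: dict = field(
        default_factory=lambda: {"breast": 10660.0, "colorectal": 13650.0}
    )
    case_fatality_by_stage: dict = field(
        default_factory=lambda: {"I": 0.17, "II": 0.40, "III": 0.64, "IV": 0.90}
    )
    benefit_scale: float = 1.0

    def __post_init__(self):
        rates = [r for r, _ in self.anchors]
        if sorted(rates) != rates or len(set(rates)) != len(rates):
            raise ValueError("anchor rates must be strictly increasing")
        if self.case_fatality_by_stage["I"] >= self.case_fatality_by_stage["IV"]:
            raise ValueError("stage I case fatality must be below stage IV")


@dataclass(frozen=True)
class LivesSaved:
    value: float
    ci_low: float | None = None
    ci_high: float | None = None


def _curve(rate: float, params: StageShiftParams) -> float:
    """Piecewise-linear response through (0,0) and the anchors, with
    secant extrapolation beyond the last anchor."""
    pts = [(0.0, 0.0), *params.anchors]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if rate <= xs[-1]:
        val = float(np.interp(rate, xs, ys))
    else:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        val = float(ys[-1] + slope * (rate - xs[-1]))
    return params.benefit_scale * val


def lives_saved(
    stage1_rate: float,
    params: StageShiftParams | None = None,
    n_iter: int = 0,
    seed: int = 0,
) -> LivesSaved:
    """Annual lives saved at a given stage I detection rate.

    Monotone non-decreasing in the rate and anchored so that the
    baseline rate reproduces the baseline lives saved exactly. With
    ``n_iter > 0`` a 95% CI is produced by normal perturbation of the
    anchor values, scaled to their published CIs.
    """
    params = params or StageShiftParams()
    if not 0.0 <= stage1_rate <= 1.0:
        raise ValueError("stage1_rate must lie in [0, 1]")
    point = _curve(stage1_rate, params)
    if n_iter <= 0:
        return LivesSaved(point)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_iter)
    for i in range(n_iter):
        anchors = []
        for rate, value in params.anchors:
            lo, hi = params.anchor_ci.get(rate, (value, value))
            sd = (hi - lo) / (2 * 1.959963984540054)
            anchors.append((rate, max(0.0, rng.normal(value, sd))))
        draws[i] = _curve(stage1_rate, replace(params, anchors=tuple(anchors)))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return LivesSaved(point, float(lo), float(hi))


def nns(absolute_risk_reduction: float) -> int:
    """Number needed to screen: reciprocal of the absolute risk
    reduction in mortality, rounded half away from zero to an integer.
    """
    if absolute_risk_reduction <= 0:
        raise ValueError("absolute risk reduction must be positive for a defined NNS")
    raw = 1.0 / absolute_risk_reduction
    return int(np.floor(raw + 0.5))


def parity_rate(target_lives: float, params: StageShiftParams | None = None) -> float:
    """Stage I detection rate needed to save ``target_lives`` per year
    (exact inverse of :func:`lives_saved` on the achievable range)."""
    params = params or StageShiftParams()
    if target_lives < 0:
        raise ValueError("target must be non-negative")
    max_rate = 1.0
    max_lives = _curve(max_rate, params)
    if target_lives > max_lives:
        raise ValueError(
            f"target {target_lives:.0f} lives/year unreachable; maximum "
            f"achievable at 100% stage I detection is {max_lives:.0f}"
        )
    pts = [(0.0, 0.0), *params.anchors]
    scaled = [(r, params.benefit_scale * v) for r, v in pts]
    for (r0, v0), (r1, v1) in zip(scaled, scaled[1:]):
        if v0 <= target_lives <= v1:
            if v1 == v0:
                return r0
            return r0 + (target_lives - v0) * (r1 - r0) / (v1 - v0)
    # beyond last anchor: invert the secant extrapolation
    (r0, v0), (r1, v1) = scaled[-2], scaled[-1]
    slope = (v1 - v0) / (r1 - r0)
    return r1 + (target_lives - v1) / slope
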