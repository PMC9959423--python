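"""Rule-based fluorosis staging from opaque/brown area ratios.

The grade follows the clinical picture: opaque-white patches appear first
and grow with severity, brown stains mark the severe end — but a brown
area only signals severe disease when a fair amount of opaque enamel is
present too, which is what the small-opaque shortcut (the first branch)
encodes.  With thresholds 0 <= theta1 < theta2 < theta3 <= 1 and a brown
tolerance delta, evaluated strictly in order:

    r_opaque <= theta1                     -> Normal
    r_opaque <= theta2 and r_brown <= delta -> Normal
    r_opaque <= theta3 and r_brown <= delta -> Stage 1
    r_brown <= delta                        -> Stage 2
    otherwise                               -> Stage 3

Defaults: theta = (0.05, 0.1, 0.3), delta = 0.007.  The ablated variant
drops the first branch (as in earlier work) and demonstrably misgrades
shadow-induced brown pixels on otherwise healthy teeth.
"""

from __future__ import annotations

from dataclasses import dataclass

from .labels import STAGE_NAMES


@dataclass
class StageThresholds:
    theta1: float = 0.05
    theta2: float = 0.1
    theta3: float = 0.3
    delta: float = 0.007

    def __post_init__(self):
        if not (0.0 <= self.theta1 < self.theta2 < self.theta3 <= 1.0):
            raise ValueError("require 0 <= theta1 < theta2 < theta3 <= 1")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")


def _check_ratios(r_opaque: float, r_brown: float) -> None:
    if not (0.0 <= r_opaque <= 1.0 and 0.0 <= r_brown <= 1.0):
        raise ValueError("ratios must lie in [0, 1]")


def classify_fluorosis(r_opaque: float, r_brown: float,
                       thresholds: StageThresholds | None = None) -> str:
    """Stage name for the given opaque/brown fractions of the tooth area."""
    t = thresholds or StageThresholds()
    _check_ratios(r_opaque, r_brown)
    if r_opaque <= t.theta1:
        return STAGE_NAMES[0]
    if r_opaque <= t.theta2 and r_brown <= t.delta:
        return STAGE_NAMES[0]
    if r_opaque <= t.theta3 and r_brown <= t.delta:
        return STAGE_NAMES[1]
    if r_brown <= t.delta:
        return STAGE_NAMES[2]
    return STAGE_NAMES[3]


def classify_fluorosis_ablated(r_opaque: float, r_brown: float,
                               thresholds: StageThresholds | None = None) -> str:
    """Staging rule without the small-opaque shortcut (prior-work variant)."""
    t = thresholds or StageThresholds()
    _check_ratios(r_opaque, r_brown)
    if r_opaque <= t.theta2 and r_brown <= t.delta:
        return STAGE_NAMES[0]
    if r_opaque <= t.theta3 and r_brown <= t.delta:
        return STAGE_NAMES[1]
    if r_brown <= t.delta:
        return STAGE_NAMES[2]
    return STAGE_NAMES[3]


def fired_branch(r_opaque: float, r_brown: float,
                 thresholds: StageThresholds | None = None) -> str:
    """Human-readable description of the rule branch that decided the stage."""
    t = thresholds or StageThresholds()
    _check_ratios(r_opaque, r_brown)
    if r_opaque <= t.theta1:
        return f"r_opaque <= theta1 ({t.theta1:g})"
    if r_opaque <= t.theta2 and r_brown <= t.delta:
        return f"r_opaque <= theta2 ({t.theta2:g}) and r_brown <= delta ({t.delta:g})"
    if r_opaque <= t.theta3 and r_brown <= t.delta:
        return f"r_opaque <= theta3 ({t.theta3:g}) and r_brown <= delta ({t.delta:g})"
    if r_brown <= t.delta:
        return f"r_brown <= delta ({t.delta:g})"
    return f"r_brown > delta ({t.delta:g})"
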