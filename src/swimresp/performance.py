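"""Critical swimming speed (Ucrit) and the solid-blocking correction.

Ucrit prorates the partially completed final step of an incremental-velocity
test:

    Ucrit = V + tf * Vi / ti

with V the highest speed swum for the full increment, Vi the velocity
increment, tf the time swum at the fatigue speed and ti the increment
duration.  Because the fish occupies part of the flume cross-section, water
accelerates around it; the raw speed is corrected multiplicatively:

    Ucrit_corrected = Ucrit * (1 + eps),  eps = tau * lambda * (A0 / AT)**1.5

where A0 = 0.25 G^2 / pi is the fish's cross-sectional area from its maximum
girth G and AT = pi r^2 the tunnel cross-section.
"""
from __future__ import annotations

import math

from .errors import FishTooLargeError, InvalidConfigError, ProtocolError
from .types import SpeedStep, TunnelGeometry, UcritResult

#: protocol defaults: 0.15 bL s-1 increments every 15 min
DEFAULT_VI = 0.15
DEFAULT_TI_S = 900.0


def _split_steps(steps: list[SpeedStep]) -> tuple[list[SpeedStep], SpeedStep]:
    if not steps:
        raise ProtocolError("no swim steps recorded")
    speeds = [s.speed_bl_s for s in steps]
    if any(b <= a for a, b in zip(speeds, speeds[1:])):
        raise InvalidConfigError("swim-step speeds must be strictly increasing")
    exhaustion = steps[-1]
    if exhaustion.completed:
        raise ProtocolError("no exhaustion step: fish never fatigued")
    for s in steps[:-1]:
        if not s.completed:
            raise ProtocolError("an interior step was not completed")
    return steps[:-1], exhaustion


def compute_ucrit(
    steps: list[SpeedStep],
    vi: float | None = None,
    ti_s: float | None = None,
) -> float:
    """Critical swim speed (bL s-1) from a recorded step schedule.

    ``vi`` and ``ti_s`` default to the schedule's own increment and the
    exhaustion step's planned duration.  A fish that fatigues during the
    first swimming step is scored with V = 0 (sub-protocol; see
    :func:`ucrit_result` for the flag).
    """
    completed, exhaustion = _split_steps(steps)
    v = completed[-1].speed_bl_s if completed else 0.0
    if vi is None:
        vi = exhaustion.speed_bl_s - v if completed else DEFAULT_VI
    if ti_s is None:
        ti_s = exhaustion.duration_planned_s
    if vi <= 0 or ti_s <= 0:
        raise InvalidConfigError("vi and ti must be positive")
    return v + exhaustion.time_swum_s * vi / ti_s


def blocking_epsilon(girth_cm: float, tunnel: TunnelGeometry) -> float:
    """Solid-blocking error eps = tau * lambda * (A0/AT)**a_exp (dimensionless)."""
    if girth_cm <= 0:
        raise InvalidConfigError("girth must be positive")
    a0 = 0.25 * girth_cm**2 / math.pi
    at = tunnel.cross_section_cm2
    if a0 >= at:
        raise FishTooLargeError(
            f"fish cross-section {a0:.1f} cm2 >= tunnel cross-section {at:.1f} cm2"
        )
    return tunnel.tau_shape * tunnel.lambda_shape * (a0 / at) ** tunnel.a_exp


def correct_ucrit(ucrit_raw: float, epsilon_s: float) -> float:
    """Apply the solid-blocking correction multiplicatively."""
    if epsilon_s < 0:
        raise InvalidConfigError("epsilon must be non-negative")
    return ucrit_raw * (1.0 + epsilon_s)


def ucrit_result(
    steps: list[SpeedStep],
    girth_cm: float,
    tunnel: TunnelGeometry,
    vi: float | None = None,
    ti_s: float | None = None,
) -> UcritResult:
    """Full Ucrit computation: raw speed, blocking factor, corrected speed."""
    completed, exhaustion = _split_steps(steps)
    raw = compute_ucrit(steps, vi=vi, ti_s=ti_s)
    eps = blocking_epsilon(girth_cm, tunnel)
    ti = ti_s if ti_s is not None else exhaustion.duration_planned_s
    return UcritResult(
        ucrit_raw=raw,
        epsilon_s=eps,
        ucrit_corrected=correct_ucrit(raw, eps),
        final_full_speed=completed[-1].speed_bl_s if completed else 0.0,
        fatigue_fraction=exhaustion.time_swum_s / ti,
        sub_protocol=not completed,
    )
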