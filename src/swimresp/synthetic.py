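"""Synthetic swim-trial generator with known ground truth.

No raw traces accompany the study this pipeline targets, so every
raw-data-dependent stage is validated against trials generated here.  The
generator emulates the measurement protocol end to end:

* closed-phase PO2 traces decline linearly at the rate implied by the true
  MO2, the effective respirometer volume and the oxygen solubility of the
  water, plus additive Gaussian sensor noise, and are never emitted below
  85% air saturation;
* ventral-aortic flow is a train of non-negative half-sine ejection pulses,
  each integrating to one true stroke volume, so the time-averaged flow is
  fH * VS * mass;
* MO2 couples to swimming speed through the same log-linear model the SMR
  extrapolation assumes, log10(MO2) = log10(SMR) + b*v, making the noise-free
  round trip exact (an optional curvature term probes robustness);
* exhaustion is placed inside the step containing the true Ucrit so that the
  prorating formula inverts it exactly;
* the 2-h recovery decays single-exponentially toward resting values with
  time constant ``epoc_tau``.

Defaults reproduce the study conditions: 9 fish per temperature group at 22
and 30 degC, 34 ppt, a 108.7-l tunnel of 120 mm radius, baseline speed 0.08
bL s-1, first swimming speed 0.35, increments of 0.15 bL s-1 every 15 min,
and between-fish variability with CV = 3*SEM/mean taken from the published
group table (n = 9 means SD = 3*SEM).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidConfigError, TraceError
from .published import TABLE1
from .respirometry import effective_volume_l, o2_solubility
from .types import (
    FishMorphometrics,
    FlowTrace,
    Phase,
    PhaseData,
    PO2Trace,
    SpeedStep,
    SyntheticTruth,
    TrialRecord,
    TunnelGeometry,
)

PO2_FLOOR_PCT = 85.0
PO2_MIN_CLOSED_S = 120.0


@dataclass(frozen=True)
class MorphConfig:
    """Truncated-at-zero normal distributions for fish morphometrics.

    Defaults emulate the study animals: subadult grouper of ~0.8-1.0 kg,
    ~40 cm fork length, girth well below the tunnel circumference, and a
    ventricle of ~0.09% body mass.
    """

    mass_mean_kg: float = 0.9
    mass_sd_kg: float = 0.1
    length_mean_cm: float = 40.0
    length_sd_cm: float = 3.0
    girth_mean_cm: float = 28.0
    girth_sd_cm: float = 2.0
    vmass_mean_g: float = 0.8
    vmass_sd_g: float = 0.12

    def __post_init__(self) -> None:
        if min(self.mass_mean_kg, self.length_mean_cm, self.girth_mean_cm,
               self.vmass_mean_g) <= 0:
            raise InvalidConfigError("distribution means must be positive")
        if min(self.mass_sd_kg, self.length_sd_cm, self.girth_sd_cm,
               self.vmass_sd_g) < 0:
            raise InvalidConfigError("distribution SDs cannot be negative")


@dataclass(frozen=True)
class ScheduleConfig:
    """Incremental-velocity protocol (speeds in bL s-1, durations in s)."""

    baseline_speed: float = 0.08
    first_speed: float = 0.35
    increment: float = 0.15
    step_duration_s: float = 900.0
    recovery_minutes_cardiac: tuple[float, ...] = (15, 30, 45, 60, 75, 90, 105, 120)
    recovery_minutes_mo2: tuple[float, ...] = (30, 60, 90, 120)


@dataclass(frozen=True)
class TrialSimConfig:
    """Trace sampling and waveform settings (config choices, not protocol)."""

    po2_rate_hz: float = 1.0
    flow_rate_hz: float = 100.0
    closed_duration_s: float = 480.0
    recovery_closed_s: float = 330.0
    flow_duration_s: float = 65.0
    min_closed_s: float = 150.0   # 2-min wait + 30 samples at 1 Hz
    min_flow_s: float = 60.0      # two 30-s counting windows
    systolic_fraction: float = 0.4
    curvature: float = 0.0        # optional quadratic term in log10(MO2) vs v
    ar1_rho: float = 0.0          # AR(1) coefficient for trace noise


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw redrawn until positive (zero SD returns the mean)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise InvalidConfigError("could not draw a positive value; check mean/SD")


def generate_fish(seed, config: MorphConfig = MorphConfig()) -> FishMorphometrics:
    """Draw one fish's morphometrics; reproducible for a fixed seed."""
    rng = _rng(seed)
    return FishMorphometrics(
        mass_kg=_truncated_normal(rng, config.mass_mean_kg, config.mass_sd_kg),
        fork_length_cm=_truncated_normal(rng, config.length_mean_cm, config.length_sd_cm),
        girth_cm=_truncated_normal(rng, config.girth_mean_cm, config.girth_sd_cm),
        ventricular_mass_g=_truncated_normal(rng, config.vmass_mean_g, config.vmass_sd_g),
    )


def _noise(rng, n: int, sd: float, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, n)
    if rho:
        out = np.empty(n)
        out[0] = eps[0]
        scale = math.sqrt(1.0 - rho**2)
        for i in range(1, n):
            out[i] = rho * out[i - 1] + scale * eps[i]
        return out
    return eps


def po2_decline_rate_pct_h(
    mo2_true: float,
    fish: FishMorphometrics,
    tunnel: TunnelGeometry,
    temp_c: float,
    salinity_ppt: float,
) -> float:
    """Closed-phase PO2 decline (% air saturation h-1) from the mass balance."""
    beta = o2_solubility(temp_c, salinity_ppt)
    return mo2_true * fish.mass_kg / (effective_volume_l(fish, tunnel) * beta) * 100.0


def simulate_po2_trace(
    mo2_true: float,
    fish: FishMorphometrics,
    tunnel: TunnelGeometry,
    temp_c: float,
    salinity_ppt: float,
    duration_s: float,
    noise_sd: float,
    seed,
    rate_hz: float = 1.0,
    phase: Phase = Phase("rest"),
    ar1_rho: float = 0.0,
) -> PO2Trace:
    """One closed-phase PO2 trace starting at 100% air saturation.

    The trace is truncated (and flagged) where it would fall below 85%; a
    decline that would cross 85% before 120 s raises, since no usable slope
    could be fit from such a phase.
    """
    if duration_s > 600.0:
        raise InvalidConfigError("closed phases must not exceed 10 min")
    rate_s = po2_decline_rate_pct_h(mo2_true, fish, tunnel, temp_c, salinity_ppt) / 3600.0
    if 100.0 - rate_s * PO2_MIN_CLOSED_S < PO2_FLOOR_PCT:
        raise TraceError("PO2 would cross 85% air saturation before 120 s")
    t = np.arange(0.0, duration_s + 0.5 / rate_hz, 1.0 / rate_hz)
    po2 = 100.0 - rate_s * t + _noise(_rng(seed), t.size, noise_sd, ar1_rho)
    truncated = False
    below = np.nonzero(po2 < PO2_FLOOR_PCT)[0]
    if below.size:
        t, po2 = t[: below[0]], po2[: below[0]]
        truncated = True
    po2 = np.clip(po2, None, 110.0)
    return PO2Trace(t, po2, temp_c, salinity_ppt, phase, truncated=truncated)


def simulate_flow_trace(
    fh_true: float,
    vs_true: float,
    mass_kg: float,
    duration_s: float,
    sample_rate_hz: float = 100.0,
    noise_sd: float = 0.0,
    seed=0,
    systolic_fraction: float = 0.4,
    phase: Phase = Phase("rest"),
    ar1_rho: float = 0.0,
) -> FlowTrace:
    """Pulsatile ventral-aortic flow: half-sine ejection pulses plus noise.

    Each pulse integrates to one stroke volume (vs_true * mass_kg ml), so the
    time-averaged flow is fh_true * vs_true * mass_kg ml min-1 within noise.
    """
    if sample_rate_hz < 50.0:
        raise InvalidConfigError("flow sampling must be >= 50 Hz")
    if not (10.0 < fh_true < 250.0):
        raise InvalidConfigError("fh_true must lie in (10, 250) beats min-1")
    period_s = 60.0 / fh_true
    if period_s * sample_rate_hz < 2.0:
        raise TraceError("pulse period shorter than 2 samples")
    pulse_s = systolic_fraction * period_s
    sv_ml = vs_true * mass_kg
    # integral of A*sin(pi*t/d) over [0, d] is 2*A*d/pi (ml s min-1);
    # divide by 60 s min-1 to get ml, hence the peak amplitude below
    amplitude = sv_ml * 60.0 * math.pi / (2.0 * pulse_s)
    n = int(round(duration_s * sample_rate_hz)) + 1
    t = np.arange(n) / sample_rate_hz
    tp = np.mod(t, period_s)
    flow = np.where(tp < pulse_s, amplitude * np.sin(math.pi * tp / pulse_s), 0.0)
    flow = flow + _noise(_rng(seed), n, noise_sd, ar1_rho)
    return FlowTrace(t, flow, sample_rate_hz, phase)


def default_truth(temp_c: float) -> SyntheticTruth:
    """Group-level ground truth matching the published group means.

    The log-linear slope is set so the model passes through (Ucrit, MMR),
    which also places the implied RMR at the baseline speed within ~1% of the
    published value.  Recovery time constants (30 min at 22 degC, 70 min at
    30 degC) reproduce the published 2-h recovery endpoints under the
    single-exponential model.
    """
    if round(temp_c) == 22:
        smr, mmr, ucrit = 44.08, 230.32, 0.70
        return SyntheticTruth(
            smr_true=smr,
            slope_b=math.log10(mmr / smr) / ucrit,
            fh_rest=33.3, fh_max=62.4,
            vs_rest=0.425, vs_max=0.589,
            ucrit_true=ucrit, epoc_tau=30.0,
            noise_sd_po2=0.05, noise_sd_flow=2.0,
            temp_c=22.0, salinity_ppt=34.0,
        )
    if round(temp_c) == 30:
        smr, mmr, ucrit = 117.71, 409.40, 0.96
        return SyntheticTruth(
            smr_true=smr,
            slope_b=math.log10(mmr / smr) / ucrit,
            fh_rest=58.3, fh_max=118.8,
            vs_rest=0.385, vs_max=0.462,
            ucrit_true=ucrit, epoc_tau=70.0,
            noise_sd_po2=0.05, noise_sd_flow=2.0,
            temp_c=30.0, salinity_ppt=34.0,
        )
    raise InvalidConfigError("default truths are defined for 22 and 30 degC")


def _cv(param: str, temp: int) -> float:
    mean, sem = TABLE1[param][temp]
    return 3.0 * sem / mean  # n = 9 -> SD = 3 * SEM


def group_truths(temp_c: float, n: int, seed) -> list[SyntheticTruth]:
    """Per-fish truths with between-fish biological variability.

    Each parameter is drawn around the group truth with the CV implied by
    the published SEMs; MMR is drawn directly and converted to the log-linear
    slope, and draws violating physiological ordering are repeated.
    """
    base = default_truth(temp_c)
    temp = int(round(temp_c))
    rng = _rng(seed)
    mmr_base = base.mo2_at(base.ucrit_true)
    truths = []
    for _ in range(n):
        for _attempt in range(1000):
            smr = _truncated_normal(rng, base.smr_true, base.smr_true * _cv("smr", temp))
            mmr = _truncated_normal(rng, mmr_base, mmr_base * _cv("mmr", temp))
            ucrit = _truncated_normal(rng, base.ucrit_true,
                                      base.ucrit_true * _cv("ucrit", temp))
            fh_rest = _truncated_normal(rng, base.fh_rest,
                                        base.fh_rest * _cv("fh_rest", temp))
            fh_max = _truncated_normal(rng, base.fh_max,
                                       base.fh_max * _cv("fh_max", temp))
            vs_rest = _truncated_normal(rng, base.vs_rest,
                                        base.vs_rest * _cv("vs_rest", temp))
            vs_max = _truncated_normal(rng, base.vs_max,
                                       base.vs_max * _cv("vs_max", temp))
            if mmr > smr and fh_max > fh_rest and vs_max >= vs_rest and ucrit > 0.40:
                break
        else:  # pragma: no cover - essentially unreachable at these CVs
            raise InvalidConfigError("could not draw a physiologically ordered fish")
        truths.append(replace(
            base,
            smr_true=smr,
            slope_b=math.log10(mmr / smr) / ucrit,
            ucrit_true=ucrit,
            fh_rest=fh_rest, fh_max=fh_max,
            vs_rest=vs_rest, vs_max=vs_max,
        ))
    return truths


def _safe_closed_duration(rate_pct_h: float, cap_s: float) -> float:
    """Longest closed phase that keeps PO2 comfortably above the 85% floor."""
    if rate_pct_h <= 0:
        return cap_s
    t85 = (100.0 - PO2_FLOOR_PCT) / rate_pct_h * 3600.0
    return min(cap_s, 0.9 * t85)


def _fh_at(truth: SyntheticTruth, speed: float, baseline: float) -> float:
    frac = np.clip((speed - baseline) / (truth.ucrit_true - baseline), 0.0, 1.0)
    return truth.fh_rest + (truth.fh_max - truth.fh_rest) * frac


def _vs_at(truth: SyntheticTruth, speed: float, baseline: float) -> float:
    frac = np.clip((speed - baseline) / (truth.ucrit_true - baseline), 0.0, 1.0)
    return truth.vs_rest + (truth.vs_max - truth.vs_rest) * frac


def simulate_trial(
    truth: SyntheticTruth,
    fish: FishMorphometrics,
    tunnel: TunnelGeometry = TunnelGeometry(),
    schedule: ScheduleConfig = ScheduleConfig(),
    sim: TrialSimConfig = TrialSimConfig(),
    seed=0,
    fish_id: str = "fish",
) -> TrialRecord:
    """Generate one complete trial: rest, swim steps, exhaustion, recovery.

    Exhaustion is placed so that the prorating formula applied to the emitted
    schedule returns ``truth.ucrit_true`` exactly.  The exhaustion-step
    measurements are emitted only when the time to fatigue accommodates them
    (PO2: the 2-min wait plus 30 samples; flow: two 30-s windows); MO2 during
    that step is the model value at Ucrit, the highest aerobic output the
    fish attains.
    """
    if truth.ucrit_true <= schedule.first_speed:
        raise InvalidConfigError("ucrit_true must exceed the first swimming speed")
    mo2_curv = (lambda v: truth.smr_true
                * 10.0 ** (truth.slope_b * min(v, truth.ucrit_true)
                           + sim.curvature * min(v, truth.ucrit_true) ** 2))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = iter(ss.spawn(512))

    # --- schedule ------------------------------------------------------
    speeds = []
    k = 0
    while True:
        v = schedule.first_speed + k * schedule.increment
        if v > truth.ucrit_true + 1e-12:
            break
        speeds.append(v)
        k += 1
    v_exh = schedule.first_speed + len(speeds) * schedule.increment
    v_last = speeds[-1]
    tf = (truth.ucrit_true - v_last) / schedule.increment * schedule.step_duration_s
    steps = [SpeedStep(v, schedule.step_duration_s, schedule.step_duration_s)
             for v in speeds]
    steps.append(SpeedStep(v_exh, schedule.step_duration_s, tf))

    def po2_phase(mo2_val, phase, cap_s):
        rate = po2_decline_rate_pct_h(mo2_val, fish, tunnel,
                                      truth.temp_c, truth.salinity_ppt)
        dur = _safe_closed_duration(rate, cap_s)
        if dur < sim.min_closed_s:
            return None
        return simulate_po2_trace(
            mo2_val, fish, tunnel, truth.temp_c, truth.salinity_ppt,
            dur, truth.noise_sd_po2, next(seeds),
            rate_hz=sim.po2_rate_hz, phase=phase, ar1_rho=sim.ar1_rho,
        )

    def flow_phase(fh, vs, phase, dur=None):
        return simulate_flow_trace(
            fh, vs, fish.mass_kg, dur or sim.flow_duration_s,
            sample_rate_hz=sim.flow_rate_hz, noise_sd=truth.noise_sd_flow,
            seed=next(seeds), systolic_fraction=sim.systolic_fraction,
            phase=phase, ar1_rho=sim.ar1_rho,
        )

    phases: list[PhaseData] = []

    # resting baseline
    rest = Phase("rest", speed_bl_s=schedule.baseline_speed)
    rmr_true = mo2_curv(schedule.baseline_speed)
    phases.append(PhaseData(rest, po2_phase(rmr_true, rest, sim.closed_duration_s),
                            flow_phase(truth.fh_rest, truth.vs_rest, rest)))

    # completed swim steps
    for v in speeds:
        ph = Phase("swim", speed_bl_s=v)
        phases.append(PhaseData(
            ph,
            po2_phase(mo2_curv(v), ph, sim.closed_duration_s),
            flow_phase(_fh_at(truth, v, schedule.baseline_speed),
                       _vs_at(truth, v, schedule.baseline_speed), ph),
        ))

    # partial exhaustion step, measured at the fish's maximum aerobic output
    exh = Phase("swim", speed_bl_s=truth.ucrit_true, exhaustion=True)
    exh_po2 = po2_phase(mo2_curv(truth.ucrit_true), exh,
                        min(sim.closed_duration_s, tf)) if tf >= sim.min_closed_s else None
    exh_flow = (flow_phase(truth.fh_max, truth.vs_max, exh, dur=min(tf, sim.flow_duration_s))
                if tf >= sim.min_flow_s else None)
    if exh_po2 is not None or exh_flow is not None:
        phases.append(PhaseData(exh, exh_po2, exh_flow))

    # 2-h recovery toward resting values
    mmr_true = mo2_curv(truth.ucrit_true)
    for minute in sorted(set(schedule.recovery_minutes_cardiac)
                         | set(schedule.recovery_minutes_mo2)):
        decay = math.exp(-minute / truth.epoc_tau)
        ph = Phase("recovery", speed_bl_s=schedule.baseline_speed, minute=float(minute))
        po2 = None
        if minute in schedule.recovery_minutes_mo2:
            mo2_rec = rmr_true + (mmr_true - rmr_true) * decay
            po2 = po2_phase(mo2_rec, ph, sim.recovery_closed_s)
        flow = None
        if minute in schedule.recovery_minutes_cardiac:
            fh_rec = truth.fh_rest + (truth.fh_max - truth.fh_rest) * decay
            vs_rec = truth.vs_rest + (truth.vs_max - truth.vs_rest) * decay
            flow = flow_phase(fh_rec, vs_rec, ph)
        if po2 is not None or flow is not None:
            phases.append(PhaseData(ph, po2, flow))

    return TrialRecord(
        fish_id=fish_id,
        fish=fish,
        tunnel=tunnel,
        temp_c=truth.temp_c,
        salinity_ppt=truth.salinity_ppt,
        steps=steps,
        phases=phases,
        ramp_c_per_h=1.0,
        truth=truth,
    )


def simulate_group(
    n_fish: int,
    temp_c: float,
    seed,
    tunnel: TunnelGeometry = TunnelGeometry(),
    morph: MorphConfig = MorphConfig(),
    schedule: ScheduleConfig = ScheduleConfig(),
    sim: TrialSimConfig = TrialSimConfig(),
    heterogeneous: bool = True,
) -> list[TrialRecord]:
    """Simulate one temperature group of complete trials.

    With ``heterogeneous=False`` every fish carries the group-level truth
    (useful for noise-free round-trip checks).
    """
    ss = np.random.SeedSequence(seed)
    truth_seed, *fish_seeds = ss.spawn(2 * n_fish + 1)
    truths = (group_truths(temp_c, n_fish, truth_seed) if heterogeneous
              else [default_truth(temp_c)] * n_fish)
    trials = []
    for i, truth in enumerate(truths):
        fish = generate_fish(fish_seeds[2 * i], morph)
        trials.append(simulate_trial(
            truth, fish, tunnel, schedule, sim,
            seed=fish_seeds[2 * i + 1],
            fish_id=f"fish_{int(round(temp_c))}C_{i:02d}",
        ))
    return trials
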