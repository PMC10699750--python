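"""Core data structures shared across the analysis pipeline.

Units follow comparative-physiology conventions throughout: oxygen consumption
(MO2) in mg O2 kg-1 h-1, heart rate (fH) in beats min-1, cardiac output (Q) in
ml min-1 kg-1, stroke volume (VS) in ml kg-1, tissue oxygen extraction
(MO2/Q) in mg O2 ml-1 blood, swimming speed in body lengths per second
(bL s-1), water oxygen in % air saturation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, TraceError


@dataclass(frozen=True)
class TunnelGeometry:
    """Blazka-type swim-tunnel geometry plus solid-blocking constants.

    ``tau_shape`` is the dimensionless factor for tunnel cross-sectional
    shape, ``lambda_shape`` the fish shape coefficient (0.5 for a streamlined
    body) and ``a_exp`` the fractional-area exponent of the blocking
    correction.
    """

    radius_mm: float = 120.0
    volume_l: float = 108.7
    tau_shape: float = 0.8
    lambda_shape: float = 0.5
    a_exp: float = 1.5

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.volume_l <= 0:
            raise InvalidConfigError("tunnel radius and volume must be positive")
        if not (0 < self.tau_shape <= 1 and 0 < self.lambda_shape <= 1):
            raise InvalidConfigError("shape factors must lie in (0, 1]")

    @property
    def radius_cm(self) -> float:
        return self.radius_mm / 10.0

    @property
    def cross_section_cm2(self) -> float:
        return math.pi * self.radius_cm**2


@dataclass(frozen=True)
class FishMorphometrics:
    """Morphometrics recorded at surgery; masses in kg/g, lengths in cm."""

    mass_kg: float
    fork_length_cm: float
    girth_cm: float
    ventricular_mass_g: float | None = None

    def __post_init__(self) -> None:
        if min(self.mass_kg, self.fork_length_cm, self.girth_cm) <= 0:
            raise InvalidConfigError("morphometrics must be positive")
        if self.ventricular_mass_g is not None and self.ventricular_mass_g < 0:
            raise InvalidConfigError("ventricular mass cannot be negative")


@dataclass(frozen=True)
class Phase:
    """Label for one measurement phase of a trial.

    ``kind`` is 'rest', 'swim' or 'recovery'; swim phases carry the speed,
    recovery phases the minute since exhaustion.  ``exhaustion`` marks the
    partial final step of the incremental-velocity test.
    """

    kind: str
    speed_bl_s: float | None = None
    minute: float | None = None
    exhaustion: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("rest", "swim", "recovery"):
            raise InvalidConfigError(f"unknown phase kind {self.kind!r}")


@dataclass(eq=False)
class PO2Trace:
    """Water oxygen (% air saturation) during one closed respirometry phase."""

    time_s: np.ndarray
    po2_pct_sat: np.ndarray
    temp_c: float
    salinity_ppt: float
    phase: Phase
    truncated: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.po2_pct_sat = np.asarray(self.po2_pct_sat, dtype=float)
        if self.time_s.shape != self.po2_pct_sat.shape or self.time_s.ndim != 1:
            raise TraceError("time and PO2 arrays must be 1-D and equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise TraceError("time must be strictly increasing")
        if np.any(self.po2_pct_sat <= 0) or np.any(self.po2_pct_sat > 110):
            raise TraceError("PO2 must lie in (0, 110] % air saturation")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(eq=False)
class FlowTrace:
    """Pulsatile ventral-aortic blood flow (ml min-1), uniformly sampled."""

    time_s: np.ndarray
    flow_ml_min: np.ndarray
    sample_rate_hz: float
    phase: Phase

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flow_ml_min = np.asarray(self.flow_ml_min, dtype=float)
        if self.time_s.shape != self.flow_ml_min.shape or self.time_s.ndim != 1:
            raise TraceError("time and flow arrays must be 1-D and equal length")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise TraceError("flow trace must be uniformly sampled")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class SlopeFit:
    """Least-squares line through a closed-phase PO2 decline."""

    slope_pct_sat_per_h: float
    intercept_pct_sat: float
    r2: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class MO2Sample:
    """One mass-specific oxygen-consumption measurement (mg O2 kg-1 h-1)."""

    mo2: float
    speed_bl_s: float | None
    phase: Phase
    r2: float
    qc_flag: str  # 'pass' | 'low_r2' | 'truncated'
    degenerate: bool = False


@dataclass(frozen=True)
class CardiacSample:
    """Heart rate, cardiac output, stroke volume and oxygen extraction for one
    phase.  The identities q = fh * vs and mo2 = 60 * q * extraction hold by
    construction."""

    fh: float
    q: float
    vs: float
    extraction: float | None
    speed_bl_s: float | None
    phase: Phase
    no_pulse: bool = False


@dataclass(frozen=True)
class SpeedStep:
    """One commanded velocity step of the incremental swim test."""

    speed_bl_s: float
    duration_planned_s: float = 900.0
    time_swum_s: float = 900.0

    def __post_init__(self) -> None:
        if not (0 <= self.time_swum_s <= self.duration_planned_s):
            raise InvalidConfigError("time swum must lie in [0, planned duration]")

    @property
    def completed(self) -> bool:
        return self.time_swum_s >= self.duration_planned_s


@dataclass(frozen=True)
class UcritResult:
    """Critical swim speed, raw and corrected for solid blocking."""

    ucrit_raw: float
    epsilon_s: float
    ucrit_corrected: float
    final_full_speed: float
    fatigue_fraction: float
    sub_protocol: bool = False


@dataclass
class PhaseData:
    """Raw traces recorded during one phase."""

    phase: Phase
    po2: PO2Trace | None = None
    flow: FlowTrace | None = None


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth physiology used by the synthetic trial generator.

    ``slope_b`` is the increase in log10(MO2) per bL s-1, so that
    MO2(v) = smr_true * 10**(slope_b * v); ``epoc_tau`` is the recovery time
    constant in minutes of the single-exponential return to resting values.
    """

    smr_true: float
    slope_b: float
    fh_rest: float
    fh_max: float
    vs_rest: float
    vs_max: float
    ucrit_true: float
    epoc_tau: float
    noise_sd_po2: float
    noise_sd_flow: float
    temp_c: float
    salinity_ppt: float

    def __post_init__(self) -> None:
        if min(self.smr_true, self.fh_rest, self.fh_max, self.vs_rest,
               self.vs_max, self.epoc_tau) <= 0:
            raise InvalidConfigError("all rates must be strictly positive")
        if self.fh_max <= self.fh_rest:
            raise InvalidConfigError("fh_max must exceed fh_rest")
        if self.vs_max < self.vs_rest:
            raise InvalidConfigError("vs_max must be >= vs_rest")
        if self.ucrit_true <= 0.35:
            raise InvalidConfigError("ucrit_true must exceed the first swimming speed")
        if self.noise_sd_po2 < 0 or self.noise_sd_flow < 0:
            raise InvalidConfigError("noise SDs cannot be negative")

    def mo2_at(self, speed_bl_s: float) -> float:
        """Model oxygen consumption at a sustained swimming speed."""
        v = min(speed_bl_s, self.ucrit_true)
        return self.smr_true * 10.0 ** (self.slope_b * v)


@dataclass
class TrialRecord:
    """One fish's complete experiment: morphometrics, schedule and traces."""

    fish_id: str
    fish: FishMorphometrics
    tunnel: TunnelGeometry
    temp_c: float
    salinity_ppt: float
    steps: list[SpeedStep]
    phases: list[PhaseData]
    ramp_c_per_h: float = 1.0
    truth: SyntheticTruth | None = None


@dataclass
class TraitSummary:
    """Per-fish derived physiology assembled from one trial."""

    fish_id: str
    temp_c: float
    smr: float | None = None
    rmr: float | None = None
    mmr: float | None = None
    aas: float | None = None
    fas: float | None = None
    aas_r: float | None = None
    fas_r: float | None = None
    fh_rest: float | None = None
    fh_max: float | None = None
    fh_scope: float | None = None
    fh_fscope: float | None = None
    vs_rest: float | None = None
    vs_max: float | None = None
    vs_scope: float | None = None
    q_rest: float | None = None
    q_max: float | None = None
    q_scope: float | None = None
    ext_rest: float | None = None
    ext_max: float | None = None
    ext_scope: float | None = None
    ucrit_raw: float | None = None
    ucrit_corrected: float | None = None
    rvm_pct: float | None = None
    mo2_2h: float | None = None
    fh_2h: float | None = None
    vs_2h: float | None = None
    q_2h: float | None = None
    ext_2h: float | None = None
    smr_fit_r2: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Q10Result:
    """Thermal sensitivity of one parameter between two temperatures."""

    parameter_name: str
    r1: float
    r2: float
    t1: float
    t2: float
    q10: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group or paired statistical test."""

    statistic: float
    df: float
    p_value: float
    method_name: str
    n1: int
    n2: int
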