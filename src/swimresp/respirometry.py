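"""Intermittent closed respirometry: PO2 slopes to mass-specific MO2.

During a closed phase the tunnel inflow is stopped and water oxygen declines
as the fish respires.  Mass-specific oxygen consumption follows from the
slope of that decline, the oxygen solubility of the water, and the effective
respirometer volume:

    MO2 = |slope| / 100 * beta * V_eff / mass      (mg O2 kg-1 h-1)

with the slope in % air saturation h-1, beta the oxygen concentration at
100% air saturation (mg O2 l-1), V_eff the tunnel volume minus the fish's
volume (density taken as 1.0 kg l-1) and mass in kg.
"""
from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .errors import DomainError, InsufficientDataError, LeakError
from .types import FishMorphometrics, MO2Sample, Phase, PO2Trace, SlopeFit, TunnelGeometry

#: lower bound on usable samples after the wait-period exclusion
MIN_SAMPLES = 30

#: r-squared below which a slope fit is flagged (samples are kept, never dropped)
R2_QC_THRESHOLD = 0.80

#: fraction of the fish's rate above which background respiration is subtracted
BACKGROUND_FRACTION_THRESHOLD = 0.01

# Garcia & Gordon (1992) combined fit of the Benson & Krause oxygen
# solubility data, ml(STP) O2 l-1 at 100% air saturation and 1 atm.
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_GG_B = (-0.00624523, -0.00737614, -0.0103410, -0.00817083)
_GG_C0 = -4.88682e-7
_O2_MG_PER_ML_STP = 1.42905  # density of O2 gas at STP

SOLUBILITY_FORMULATION = "garcia_gordon_1992_benson_krause_fit"


def o2_solubility(temp_c: float, salinity_ppt: float) -> float:
    """Oxygen concentration (mg O2 l-1) at 100% air saturation.

    Monotonically decreasing in both temperature and salinity over the valid
    range 0-40 degC and 0-40 ppt.
    """
    if not (0.0 <= temp_c <= 40.0):
        raise DomainError(f"temperature {temp_c} degC outside [0, 40]")
    if not (0.0 <= salinity_ppt <= 40.0):
        raise DomainError(f"salinity {salinity_ppt} ppt outside [0, 40]")
    ts = np.log((298.15 - temp_c) / (273.15 + temp_c))
    ln_c = 0.0
    for i, a in enumerate(_GG_A):
        ln_c += a * ts**i
    b_term = 0.0
    for i, b in enumerate(_GG_B):
        b_term += b * ts**i
    ln_c += salinity_ppt * b_term + _GG_C0 * salinity_ppt**2
    return float(np.exp(ln_c) * _O2_MG_PER_ML_STP)


def effective_volume_l(fish: FishMorphometrics, tunnel: TunnelGeometry) -> float:
    """Respirometer volume minus fish volume at a body density of 1.0 kg l-1."""
    v = tunnel.volume_l - fish.mass_kg / 1.0
    if v <= 0:
        raise DomainError("fish volume meets or exceeds tunnel volume")
    return v


def fit_po2_slope(trace: PO2Trace, wait_period_s: float = 120.0) -> SlopeFit:
    """Ordinary least-squares line on (time, PO2) after the wait period.

    The first ``wait_period_s`` seconds of every closed phase are excluded to
    let the tunnel mix.  r-squared is the squared Pearson correlation of the
    retained points; an all-constant trace yields slope 0, r2 0 and the
    degenerate flag.
    """
    if trace.duration_s <= wait_period_s:
        raise InsufficientDataError("trace does not extend past the wait period")
    mask = trace.time_s >= trace.time_s[0] + wait_period_s
    t = trace.time_s[mask]
    y = trace.po2_pct_sat[mask]
    if t.size < MIN_SAMPLES:
        raise InsufficientDataError(
            f"only {t.size} samples after wait-period exclusion (need {MIN_SAMPLES})"
        )
    if np.ptp(y) == 0.0:
        return SlopeFit(0.0, float(y[0]), 0.0, int(t.size), degenerate=True)
    res = sstats.linregress(t, y)
    r2 = float(res.rvalue**2)
    return SlopeFit(
        slope_pct_sat_per_h=float(res.slope * 3600.0),
        intercept_pct_sat=float(res.intercept),
        r2=r2,
        n_points=int(t.size),
    )


def compute_mo2(
    fit: SlopeFit,
    beta: float,
    fish: FishMorphometrics,
    tunnel: TunnelGeometry,
    phase: Phase = Phase("rest"),
    truncated: bool = False,
    positive_slope_tol_pct_h: float = 1.0,
) -> MO2Sample:
    """Convert a PO2 slope into mass-specific oxygen consumption.

    A positive slope beyond ``positive_slope_tol_pct_h`` indicates a leak or
    flush contamination and raises; a small positive slope (noise) clips to
    MO2 = 0.  r2 < 0.80 flags the sample as ``low_r2`` (kept, never dropped).
    """
    if fit.slope_pct_sat_per_h > positive_slope_tol_pct_h:
        raise LeakError(
            f"PO2 rose at {fit.slope_pct_sat_per_h:.3g} % sat h-1 during a closed phase"
        )
    v_eff = effective_volume_l(fish, tunnel)
    mo2 = max(0.0, -fit.slope_pct_sat_per_h) / 100.0 * beta * v_eff / fish.mass_kg
    if fit.r2 < R2_QC_THRESHOLD:
        qc = "low_r2"
    elif truncated:
        qc = "truncated"
    else:
        qc = "pass"
    return MO2Sample(
        mo2=mo2,
        speed_bl_s=phase.speed_bl_s,
        phase=phase,
        r2=fit.r2,
        qc_flag=qc,
        degenerate=fit.degenerate,
    )


def background_check(
    empty_tunnel_trace: PO2Trace,
    fish_sample: MO2Sample,
    fish: FishMorphometrics,
    tunnel: TunnelGeometry,
    wait_period_s: float = 120.0,
) -> tuple[float, MO2Sample]:
    """Microbial (background) respiration as a fraction of the fish's MO2.

    The background rate is measured with no fish in the tunnel (full volume).
    When the fraction reaches 1% the fish's MO2 is adjusted by subtraction;
    below that it is recorded but left unadjusted.
    """
    fit = fit_po2_slope(empty_tunnel_trace, wait_period_s)
    beta = o2_solubility(empty_tunnel_trace.temp_c, empty_tunnel_trace.salinity_ppt)
    bg_mg_per_h = max(0.0, -fit.slope_pct_sat_per_h) / 100.0 * beta * tunnel.volume_l
    fish_mg_per_h = fish_sample.mo2 * fish.mass_kg
    fraction = bg_mg_per_h / fish_mg_per_h if fish_mg_per_h > 0 else 0.0
    if fraction >= BACKGROUND_FRACTION_THRESHOLD:
        adjusted = MO2Sample(
            mo2=fish_sample.mo2 - bg_mg_per_h / fish.mass_kg,
            speed_bl_s=fish_sample.speed_bl_s,
            phase=fish_sample.phase,
            r2=fish_sample.r2,
            qc_flag=fish_sample.qc_flag,
            degenerate=fish_sample.degenerate,
        )
        return fraction, adjusted
    return fraction, fish_sample


def mo2_samples_from_trial(trial, wait_period_s: float = 120.0) -> list[MO2Sample]:
    """Fit every closed-phase PO2 trace of a trial and convert to MO2."""
    samples = []
    for ph in trial.phases:
        if ph.po2 is None:
            continue
        fit = fit_po2_slope(ph.po2, wait_period_s)
        beta = o2_solubility(ph.po2.temp_c, ph.po2.salinity_ppt)
        samples.append(
            compute_mo2(fit, beta, trial.fish, trial.tunnel,
                        phase=ph.phase, truncated=ph.po2.truncated)
        )
    return samples
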