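"""Per-fish trait assembly: metabolic rates, scopes, cardiac extremes, RVM, Q10.

Standard metabolic rate is estimated the classical way for swim-tunnel data:
log10(MO2) is regressed on swimming speed over the sustained swim steps and
extrapolated back to zero speed, so SMR = 10**intercept.  Resting metabolic
rate (RMR) is the measurement at the near-zero baseline speed and includes
postural/holding costs, hence SMR <= RMR is expected.  Aerobic scopes are
AAS = MMR - SMR and FAS = MMR / SMR, with the "_R" variants substituting RMR.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .cardiac import cardiac_samples_from_trial
from .errors import DomainError, InsufficientDataError, ProtocolError
from .performance import ucrit_result
from .respirometry import mo2_samples_from_trial
from .types import MO2Sample, Q10Result, TraitSummary, TrialRecord

#: minute of the recovery window reported as the 2-h value; samples from
#: RECOVERY_MIN_MINUTE onward qualify, the one nearest 120 min is used
RECOVERY_MINUTE = 120.0
RECOVERY_MIN_MINUTE = 105.0


@dataclass(frozen=True)
class SMRFit:
    """Back-extrapolated standard metabolic rate with fit diagnostics."""

    smr: float
    slope_per_bl_s: float
    r2: float
    n_points: int
    negative_slope: bool = False


def estimate_smr(
    samples: list[MO2Sample],
    log_base: float = 10.0,
    include_exhaustion: bool = False,
    include_baseline: bool = False,
) -> SMRFit:
    """SMR from the log(MO2)-vs-speed regression over sustained swim steps.

    By default only pre-exhaustion swimming samples enter the fit and at
    least three are required.  For fish that fatigued after few increments
    the exhaustion-step measurement and, as a last resort, the resting
    baseline point can be admitted (callers flag this).  A negative fitted
    slope (metabolism falling with speed) is flagged, not rejected.
    """
    pts = [
        s for s in samples
        if s.mo2 > 0 and s.speed_bl_s is not None and (
            (s.phase.kind == "swim"
             and (include_exhaustion or not s.phase.exhaustion))
            or (include_baseline and s.phase.kind == "rest")
        )
    ]
    if len(pts) < 3:
        raise InsufficientDataError("need >= 3 sustained swimming samples for SMR")
    v = np.array([s.speed_bl_s for s in pts])
    logy = np.log(np.array([s.mo2 for s in pts])) / math.log(log_base)
    res = sstats.linregress(v, logy)
    return SMRFit(
        smr=float(log_base**res.intercept),
        slope_per_bl_s=float(res.slope),
        r2=float(res.rvalue**2) if np.ptp(logy) > 0 else 0.0,
        n_points=len(pts),
        negative_slope=res.slope < 0,
    )


def compute_rvm(ventricular_mass_g: float, fish_mass_g: float) -> float:
    """Relative ventricular mass: ventricle as % of body mass (same units in)."""
    if fish_mass_g <= 0 or ventricular_mass_g < 0:
        raise DomainError("masses must be positive")
    if ventricular_mass_g >= fish_mass_g:
        raise DomainError("ventricular mass must be below body mass")
    return ventricular_mass_g / fish_mass_g * 100.0


def compute_q10(r1: float, t1: float, r2: float, t2: float,
                parameter_name: str = "") -> Q10Result:
    """Q10 = (R2/R1)**(10/(T2-T1)) — the fold change per 10 degC.

    The expression is orientation-invariant: swapping (r1, t1) with (r2, t2)
    leaves the result unchanged.
    """
    if r1 <= 0 or r2 <= 0:
        raise DomainError("rates must be strictly positive")
    if t1 == t2:
        raise DomainError("Q10 undefined at equal temperatures")
    q10 = (r2 / r1) ** (10.0 / (t2 - t1))
    return Q10Result(parameter_name, r1, r2, t1, t2, q10)


def _nearest_recovery(samples, attr_phase=lambda s: s.phase):
    picks = [s for s in samples if attr_phase(s).kind == "recovery"
             and attr_phase(s).minute is not None
             and attr_phase(s).minute >= RECOVERY_MIN_MINUTE]
    if not picks:
        return None
    return min(picks, key=lambda s: abs(attr_phase(s).minute - RECOVERY_MINUTE))


def summarize_traits(
    trial: TrialRecord,
    wait_period_s: float = 120.0,
    log_base: float = 10.0,
) -> TraitSummary:
    """Assemble the full per-fish trait summary from one trial record.

    MMR is the maximum single-step MO2 across swim steps (including the
    partial exhaustion step when measured); cardiac maxima are likewise the
    per-phase maxima.  Scope identities (aas = mmr - smr, *_scope =
    *_max - *_rest) hold exactly by construction.  Physiological ordering
    violations (e.g. SMR > RMR) are flagged, never silently fixed.
    """
    mo2 = mo2_samples_from_trial(trial, wait_period_s)
    cardiac = cardiac_samples_from_trial(trial, mo2)
    flags: list[str] = []

    rest_mo2 = [s for s in mo2 if s.phase.kind == "rest"]
    rest_card = [s for s in cardiac if s.phase.kind == "rest"]
    if not rest_mo2 or not rest_card:
        raise ProtocolError("trial has no rest-phase measurements")
    swim_mo2 = [s for s in mo2 if s.phase.kind == "swim"]
    swim_card = [s for s in cardiac if s.phase.kind == "swim"]
    if not swim_mo2 or not swim_card:
        raise ProtocolError("trial has no swimming measurements")

    rmr = rest_mo2[0].mo2
    mmr = max(s.mo2 for s in swim_mo2)
    try:
        smr_fit = estimate_smr(mo2, log_base=log_base)
    except InsufficientDataError:
        # fish that fatigued after few increments: widen the fit, flagged
        try:
            smr_fit = estimate_smr(mo2, log_base=log_base, include_exhaustion=True)
            flags.append("smr_fit_includes_exhaustion")
        except InsufficientDataError:
            smr_fit = estimate_smr(mo2, log_base=log_base,
                                   include_exhaustion=True, include_baseline=True)
            flags.append("smr_fit_includes_baseline")
    smr = smr_fit.smr
    if smr_fit.negative_slope:
        flags.append("smr_negative_slope")
    if not (mmr >= rmr >= smr > 0):
        flags.append("metabolic_ordering_violation")
    for s in mo2:
        if s.qc_flag != "pass":
            flags.append(f"mo2_{s.qc_flag}_{s.phase.kind}")

    rest = rest_card[0]
    fh_max = max(s.fh for s in swim_card)
    vs_max = max(s.vs for s in swim_card)
    q_max = max(s.q for s in swim_card)
    ext_pairs = [s.extraction for s in swim_card if s.extraction is not None]
    ext_max = max(ext_pairs) if ext_pairs else None

    uc = ucrit_result(trial.steps, trial.fish.girth_cm, trial.tunnel)
    if uc.sub_protocol:
        flags.append("sub_protocol_exhaustion")

    rvm = None
    if trial.fish.ventricular_mass_g is not None:
        rvm = compute_rvm(trial.fish.ventricular_mass_g, trial.fish.mass_kg * 1000.0)

    rec_mo2 = _nearest_recovery(mo2)
    rec_card = _nearest_recovery(cardiac)

    return TraitSummary(
        fish_id=trial.fish_id,
        temp_c=trial.temp_c,
        smr=smr,
        rmr=rmr,
        mmr=mmr,
        aas=mmr - smr,
        fas=mmr / smr,
        aas_r=mmr - rmr,
        fas_r=mmr / rmr,
        fh_rest=rest.fh,
        fh_max=fh_max,
        fh_scope=fh_max - rest.fh,
        fh_fscope=fh_max / rest.fh if rest.fh > 0 else None,
        vs_rest=rest.vs,
        vs_max=vs_max,
        vs_scope=vs_max - rest.vs,
        q_rest=rest.q,
        q_max=q_max,
        q_scope=q_max - rest.q,
        ext_rest=rest.extraction,
        ext_max=ext_max,
        ext_scope=(ext_max - rest.extraction
                   if ext_max is not None and rest.extraction is not None else None),
        ucrit_raw=uc.ucrit_raw,
        ucrit_corrected=uc.ucrit_corrected,
        rvm_pct=rvm,
        mo2_2h=rec_mo2.mo2 if rec_mo2 else None,
        fh_2h=rec_card.fh if rec_card else None,
        vs_2h=rec_card.vs if rec_card else None,
        q_2h=rec_card.q if rec_card else None,
        ext_2h=rec_card.extraction if rec_card else None,
        smr_fit_r2=smr_fit.r2,
        flags=flags,
    )
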