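"""Heart rate, cardiac output, stroke volume and tissue oxygen extraction.

Heart rate is obtained the way it is read off a chart trace: systolic peaks
are counted during two 30-s windows of the closed phase and the mean count
is doubled to beats min-1.  Cardiac output is the time-averaged ventral
aortic flow normalised to body mass; stroke volume is Q/fH and tissue oxygen
extraction MO2/Q, with the explicit factor of 60 reconciling the per-hour
MO2 and per-minute Q units.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidConfigError, ProbeError, TraceError
from .types import CardiacSample, FlowTrace, MO2Sample, Phase

#: minutes per hour — reconciles MO2 (per hour) with Q (per minute) in
#: extraction = MO2 / (60 * Q); asserted here because the unit bookkeeping is
#: easy to drop silently.
MIN_PER_H = 60.0
assert MIN_PER_H == 60.0

#: default counting-window length, seconds
WINDOW_S = 30.0

#: adaptive threshold percentiles (midpoint of the two is the threshold)
THRESHOLD_PCT = (10.0, 90.0)

#: refractory period as a fraction of the initial median inter-peak interval
REFRACTORY_FRACTION = 0.25

#: required peak prominence as a fraction of the 10th-90th percentile range;
#: rejects sensor-noise wiggles riding on a systolic lobe
PROMINENCE_FRACTION = 0.5


@dataclass(frozen=True)
class PeakDetection:
    """Systolic peaks found in one counting window."""

    count: int
    times_s: np.ndarray
    threshold: float | None
    refractory_s: float | None
    no_pulse: bool = False


def detect_systolic_peaks(
    trace: FlowTrace, window: tuple[float, float] | None = None
) -> PeakDetection:
    """Count systolic peaks within a window of a flow trace.

    Peaks are local maxima above an adaptive threshold (midpoint of the 10th
    and 90th amplitude percentiles within the window), separated by a
    refractory period of 0.25 x the median inter-peak interval of an initial
    pass.  A flat window returns zero peaks with the no-pulse flag.
    """
    t0, t1 = (trace.time_s[0], trace.time_s[-1]) if window is None else window
    if t0 < trace.time_s[0] - 1e-9 or t1 > trace.time_s[-1] + 1e-9:
        raise TraceError("window extends outside the trace")
    i0, i1 = np.searchsorted(trace.time_s, [t0, t1])
    x = trace.flow_ml_min[i0:i1]
    t = trace.time_s[i0:i1]
    if x.size < 3:
        raise TraceError("window contains too few samples")
    p_lo, p_hi = np.percentile(x, THRESHOLD_PCT)
    if p_hi - p_lo <= 1e-9 * max(1.0, abs(p_hi)):
        return PeakDetection(0, np.empty(0), None, None, no_pulse=True)
    threshold = 0.5 * (p_lo + p_hi)
    prominence = PROMINENCE_FRACTION * (p_hi - p_lo)
    idx, _ = find_peaks(x, height=threshold, prominence=prominence)
    if idx.size < 2:
        return PeakDetection(int(idx.size), t[idx], threshold, None,
                             no_pulse=idx.size == 0)
    median_ipi = float(np.median(np.diff(t[idx])))
    refractory_s = REFRACTORY_FRACTION * median_ipi
    distance = max(1, int(round(refractory_s * trace.sample_rate_hz)))
    idx, _ = find_peaks(x, height=threshold, prominence=prominence,
                        distance=distance)
    return PeakDetection(int(idx.size), t[idx], threshold, refractory_s)


def compute_fh(
    trace: FlowTrace,
    window1: tuple[float, float] | None = None,
    window2: tuple[float, float] | None = None,
) -> tuple[float, bool]:
    """Heart rate (beats min-1) from two 30-s counting windows.

    Defaults to the first and last 30 s of the trace.  Returns the rate and a
    no-pulse flag (both windows empty).  fh = mean(count1, count2) * 2.
    """
    t0, t_end = trace.time_s[0], trace.time_s[-1]
    if window1 is None:
        window1 = (t0, t0 + WINDOW_S)
    if window2 is None:
        window2 = (t_end - WINDOW_S, t_end)
    if window1[1] > window2[0] + 1e-9:
        raise InvalidConfigError("counting windows overlap")
    d1 = detect_systolic_peaks(trace, window1)
    d2 = detect_systolic_peaks(trace, window2)
    no_pulse = d1.count == 0 and d2.count == 0
    fh = (d1.count + d2.count) / 2.0 * (60.0 / WINDOW_S)
    return fh, no_pulse


def compute_q(
    trace: FlowTrace,
    mass_kg: float,
    window: tuple[float, float] | None = None,
) -> float:
    """Cardiac output (ml min-1 kg-1): time-averaged flow over body mass."""
    if window is None:
        x = trace.flow_ml_min
    else:
        i0, i1 = np.searchsorted(trace.time_s, window)
        x = trace.flow_ml_min[i0:i1]
        if (window[1] - window[0]) < WINDOW_S:
            raise InvalidConfigError("averaging window must be at least 30 s")
    mean_flow = float(np.mean(x))
    if mean_flow < 0:
        raise ProbeError("negative mean flow — check probe orientation")
    return mean_flow / mass_kg


def compute_vs(q: float, fh: float) -> float:
    """Stroke volume (ml kg-1) = Q / fH."""
    if fh <= 0:
        raise ProbeError("stroke volume undefined at zero heart rate")
    return q / fh


def compute_extraction(mo2: float, q: float) -> float:
    """Tissue oxygen extraction (mg O2 ml-1 blood) = MO2 / (60 * Q)."""
    if q <= 0:
        raise ProbeError("extraction undefined at zero cardiac output")
    return mo2 / (MIN_PER_H * q)


def cardiac_sample(
    trace: FlowTrace,
    mass_kg: float,
    mo2_sample: MO2Sample | None = None,
    phase: Phase | None = None,
) -> CardiacSample:
    """Assemble fH, Q, VS and (when MO2 is co-timed) extraction for a phase."""
    fh, no_pulse = compute_fh(trace)
    q = compute_q(trace, mass_kg)
    vs = compute_vs(q, fh) if fh > 0 else float("nan")
    extraction = None
    if mo2_sample is not None and q > 0:
        extraction = compute_extraction(mo2_sample.mo2, q)
    return CardiacSample(
        fh=fh,
        q=q,
        vs=vs,
        extraction=extraction,
        speed_bl_s=(phase or trace.phase).speed_bl_s,
        phase=phase or trace.phase,
        no_pulse=no_pulse,
    )


def cardiac_samples_from_trial(trial, mo2_samples=None) -> list[CardiacSample]:
    """Cardiac samples for every phase of a trial carrying a flow trace.

    MO2 samples are matched to flow traces by phase label so that extraction
    uses co-timed measurements.
    """
    by_phase = {s.phase: s for s in (mo2_samples or [])}
    out = []
    for ph in trial.phases:
        if ph.flow is None:
            continue
        out.append(
            cardiac_sample(ph.flow, trial.fish.mass_kg,
                           mo2_sample=by_phase.get(ph.phase), phase=ph.phase)
        )
    return out
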