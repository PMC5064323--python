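"""Response-timescale metrics: responsive time (RT) and sustaining time (ST).

RT is the interval from microsaccade onset to the peak of the evoked
network-averaged V1 rate.  ST is the interval from that peak to the first
subsequent crossing of the half-high level — the midpoint between the peak
and the fixation baseline — during the decay back to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ResponseTrace

__all__ = ["ResponseTiming", "NoPeakError", "NoDecayError", "measure"]

#: A response must exceed baseline by this fraction of the saturation rate
#: (0.1 % of alpha) to count as a response at all.
RESPONSE_TOLERANCE_FRACTION = 1e-3


class NoPeakError(ValueError):
    """The trace never rises detectably above baseline after the event."""


class NoDecayError(ValueError):
    """The trace never falls back to half-high before the window ends."""


@dataclass(frozen=True)
class ResponseTiming:
    """RT/ST measurement for one microsaccade event.

    ``half_high = baseline + (peak_rate - baseline) / 2``; both times in ms.
    """

    RT: float
    ST: float
    peak_rate: float
    half_high: float
    baseline: float
    t_event: float
    t_peak: float


def measure(trace: ResponseTrace, event_index: int = 0,
            alpha: float = 200.0) -> ResponseTiming:
    """Extract RT and ST for the ``event_index``-th microsaccade of a trace.

    The peak is the global maximum of ``pop_rate`` on the window from just
    after the event to the next event (or the end of the trace); ties are
    broken toward the earliest time.  The half-high crossing is located with
    linear interpolation between samples.

    Parameters
    ----------
    trace : ResponseTrace
        Simulated (or synthetic) population-rate trace with its baseline.
    event_index : int
        Which event of the trace's protocol to measure.
    alpha : float
        Saturation rate used to scale the response-detection tolerance.

    Raises
    ------
    NoPeakError
        If the windowed maximum does not exceed ``baseline`` by 0.1 % of
        ``alpha``.
    NoDecayError
        If the rate never falls below half-high before the window ends.
    """
    times = trace.event_times
    if not 0 <= event_index < len(times):
        raise IndexError(f"trace has {len(times)} events, asked for {event_index}")
    t_event = float(times[event_index])
    t_end = float(times[event_index + 1]) if event_index + 1 < len(times) \
        else float(trace.t[-1])

    window = (trace.t > t_event) & (trace.t <= t_end)
    tw = trace.t[window]
    pw = trace.pop_rate[window]
    if len(tw) < 2:
        raise NoPeakError("window after the event contains fewer than 2 samples")

    i_peak = int(np.argmax(pw))  # argmax returns the first (earliest) maximum
    peak = float(pw[i_peak])
    baseline = float(trace.baseline)
    if peak < baseline + RESPONSE_TOLERANCE_FRACTION * alpha:
        raise NoPeakError(
            f"no response: peak {peak:.4f} within tolerance of baseline "
            f"{baseline:.4f}"
        )

    half_high = baseline + (peak - baseline) / 2.0
    below = np.nonzero(pw[i_peak:] < half_high)[0]
    if len(below) == 0:
        raise NoDecayError(
            f"rate never fell below half-high {half_high:.4f} before "
            f"t = {t_end:.1f} ms"
        )
    i_cross = i_peak + int(below[0])
    # linear interpolation between the last sample above and first below
    t1, t2 = tw[i_cross - 1], tw[i_cross]
    p1, p2 = pw[i_cross - 1], pw[i_cross]
    t_half = float(t1 + (half_high - p1) / (p2 - p1) * (t2 - t1))

    t_peak = float(tw[i_peak])
    return ResponseTiming(RT=t_peak - t_event, ST=t_half - t_peak,
                          peak_rate=peak, half_high=half_high,
                          baseline=baseline, t_event=t_event, t_peak=t_peak)
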