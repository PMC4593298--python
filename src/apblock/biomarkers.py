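"""Action-potential biomarkers and abnormality detection.

APD_p (action potential duration at p% repolarisation) is measured from the
instant of maximum upstroke velocity to the first subsequent downward
crossing of the amplitude-relative threshold peak - (p/100)*(peak - rest),
with linear interpolation between the bracketing samples.  If the trace
never recrosses the threshold the APD is reported as absent (None), never
as zero or a sentinel.

Abnormality flags mirror what a safety pharmacologist would be warned
about: APD alternans between the final two paces, failure to depolarise
(no upstroke reaches the peak threshold) and failure to repolarise (an
action potential fires but never recovers within the pace).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import Trace

__all__ = [
    "Biomarkers",
    "AbnormalityCode",
    "AbnormalityMessage",
    "compute_biomarkers",
    "detect_abnormalities",
    "ALTERNANS_TOL_MS",
    "DEPOL_THRESHOLD_MV",
]

# Beat-to-beat APD90 difference beyond which alternans is flagged.
ALTERNANS_TOL_MS = 1.0
# Peak voltage below which the pace is considered a failed depolarisation.
DEPOL_THRESHOLD_MV = 0.0
# The membrane must be back below this level by the end of the pace,
# otherwise the cell has failed to repolarise even if a nominal APD90
# threshold crossing occurred (e.g. oscillation about a depolarized plateau).
REPOL_THRESHOLD_MV = -60.0


@dataclass(frozen=True)
class Biomarkers:
    """Scalar summaries of one paced action potential."""

    apd90: Optional[float]  # ms, absent if 90% repolarisation never occurs
    apd50: Optional[float]  # ms
    peak_v: float  # mV
    rest_v: float  # mV (voltage at trace start, pre-stimulus)
    dvdt_max: float  # mV/ms, max forward-difference slope
    amplitude: float  # mV, peak_v - rest_v

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if (self.apd50 is not None and self.apd90 is not None
                and self.apd50 > self.apd90 + 1e-9):
            raise ValueError("apd50 cannot exceed apd90")


class AbnormalityCode(enum.Enum):
    ALTERNANS = "ALTERNANS"
    DEPOLARISATION_FAILURE = "DEPOLARISATION_FAILURE"
    REPOLARISATION_FAILURE = "REPOLARISATION_FAILURE"


@dataclass(frozen=True)
class AbnormalityMessage:
    code: AbnormalityCode
    detail: str

    def __str__(self) -> str:
        return f"{self.code.value}: {self.detail}"


def _apd(times: np.ndarray, volts: np.ndarray, i_up: int, peak_v: float,
         amplitude: float, percent: float) -> Optional[float]:
    """Time from upstroke to first downward crossing of the p% threshold."""
    thresh = peak_v - (percent / 100.0) * amplitude
    v = volts[i_up:]
    t = times[i_up:]
    # first index where we are above threshold (the AP proper), then the
    # first downward crossing after it
    above = v > thresh
    if not above.any():
        return None
    i_first_above = int(np.argmax(above))
    down = np.flatnonzero((v[i_first_above:-1] > thresh)
                          & (v[i_first_above + 1:] <= thresh))
    if down.size == 0:
        return None
    i = i_first_above + int(down[0])
    # linear interpolation between samples i and i+1
    v0, v1 = v[i], v[i + 1]
    t_cross = t[i] + (v0 - thresh) / (v0 - v1) * (t[i + 1] - t[i])
    return float(t_cross - times[i_up])


def compute_biomarkers(trace: Trace) -> Biomarkers:
    """Compute APD90/APD50, peak, rest, max upstroke velocity and amplitude."""
    times = trace.times
    volts = trace.voltages
    if len(times) < 3:
        raise ValueError(f"trace must have at least 3 samples, got {len(times)}")

    rest_v = float(volts[0])
    peak_v = float(volts.max())
    amplitude = peak_v - rest_v
    slopes = np.diff(volts) / np.diff(times)
    dvdt_max = float(slopes.max())
    # the max forward-difference slope lives on [t_i, t_{i+1}]; the upstroke
    # lands at t_{i+1}, which is where the APD clock starts
    i_up = int(np.argmax(slopes)) + 1

    apd90 = _apd(times, volts, i_up, peak_v, amplitude, 90.0)
    apd50 = _apd(times, volts, i_up, peak_v, amplitude, 50.0)
    if apd50 is not None and apd90 is not None and apd50 > apd90:
        # square-pulse degenerate case: all thresholds crossed within one step
        apd50 = apd90
    return Biomarkers(
        apd90=apd90, apd50=apd50, peak_v=peak_v, rest_v=rest_v,
        dvdt_max=dvdt_max, amplitude=amplitude,
    )


def detect_abnormalities(
    last: Biomarkers,
    previous: Optional[Biomarkers],
    last_trace: Trace,
    alternans_tol: float = ALTERNANS_TOL_MS,
    depol_threshold: float = DEPOL_THRESHOLD_MV,
    repol_threshold: float = REPOL_THRESHOLD_MV,
) -> list[AbnormalityMessage]:
    """Flag alternans and de/re-polarisation failure on the final pace(s).

    ``previous`` is the biomarkers of the second-to-last pace when at least
    two paces were run; alternans is only assessable with both APD90s
    present.  Repolarisation failure fires either when no 90% threshold
    crossing occurs, or when the membrane is still above ``repol_threshold``
    at the end of the pace (a depolarized plateau with oscillations can
    produce a nominal crossing without genuine recovery).
    """
    messages: list[AbnormalityMessage] = []
    end_v = float(last_trace.voltages[-1])

    if last.peak_v < depol_threshold:
        messages.append(AbnormalityMessage(
            AbnormalityCode.DEPOLARISATION_FAILURE,
            f"peak voltage {last.peak_v:.2f} mV never reached the "
            f"{depol_threshold:.0f} mV depolarisation threshold",
        ))
    elif last.apd90 is None:
        messages.append(AbnormalityMessage(
            AbnormalityCode.REPOLARISATION_FAILURE,
            f"action potential (peak {last.peak_v:.2f} mV) did not "
            f"repolarise to 90% within the pace",
        ))
    elif end_v > repol_threshold:
        messages.append(AbnormalityMessage(
            AbnormalityCode.REPOLARISATION_FAILURE,
            f"membrane still at {end_v:.2f} mV at the end of the pace "
            f"(threshold {repol_threshold:.0f} mV): no genuine recovery",
        ))

    if (previous is not None and last.apd90 is not None
            and previous.apd90 is not None):
        diff = abs(last.apd90 - previous.apd90)
        if diff > alternans_tol:
            messages.append(AbnormalityMessage(
                AbnormalityCode.ALTERNANS,
                f"APD90 alternated by {diff:.2f} ms between the final two "
                f"paces ({previous.apd90:.2f} vs {last.apd90:.2f} ms)",
            ))
    return messages
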