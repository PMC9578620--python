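"""Breathing-pattern irregularity quantification and the 4-group taxonomy.

A signal's irregularity value is the mean of two standard deviations, one
over its peak series and one over its valley series.  Computed on extremum
*amplitudes* it measures breath-depth variability (amplitude
irregularity); computed on peak-to-peak and valley-to-valley *periods* it
measures timing variability (phase irregularity).  A cohort is partitioned
into four disjoint groups of equal size by ranking: the strongest combined
irregularity becomes ``type3``, the strongest period irregularity
``type1``, the strongest amplitude irregularity ``type2``, and the weakest
combined irregularity ``regular``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import detrend as scipy_detrend, find_peaks

from .errors import InsufficientCyclesError, InvalidCohortError
from .signal import RespirationSignal

#: default minimum peak-to-peak separation; shorter than any plausible breath
DEFAULT_MIN_SEPARATION_S = 1.5
#: default prominence threshold in z-units
DEFAULT_MIN_PROMINENCE = 0.2


@dataclass
class IrregularityProfile:
    """Per-signal extremum lists, irregularity values and group label."""

    signal_id: str
    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    valley_times: np.ndarray
    valley_amplitudes: np.ndarray
    amplitude_irregularity: float
    phase_irregularity: float
    combined_irregularity: float = float("nan")
    group: str | None = None
    generating_group: str | None = field(default=None, repr=False)


def _alternate(peaks: np.ndarray, valleys: np.ndarray, values: np.ndarray):
    """Enforce strict peak/valley alternation by dropping the lesser
    (for peaks) or greater (for valleys) of two same-kind neighbours."""
    events = [(int(i), "p") for i in peaks] + [(int(i), "v") for i in valleys]
    events.sort()
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx = kept[-1][0]
            better = (
                values[idx] > values[prev_idx]
                if kind == "p"
                else values[idx] < values[prev_idx]
            )
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    p = np.array([i for i, k in kept if k == "p"], dtype=int)
    v = np.array([i for i, k in kept if k == "v"], dtype=int)
    return p, v


def detect_extrema(
    signal: RespirationSignal,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    min_prominence: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of alternating peaks and valleys.

    Prominence defaults to 0.2 of the signal's own SD so raw (non
    z-scored) traces are handled on the same relative footing.
    """
    x = signal.samples
    if x.size < 3:
        raise InsufficientCyclesError("signal too short for extremum detection")
    if min_prominence is None:
        sd = float(np.std(x))
        min_prominence = DEFAULT_MIN_PROMINENCE * (sd if sd > 0 else 1.0)
    distance = max(1, int(round(min_separation_s * signal.sampling_rate_hz)))
    peaks, _ = find_peaks(x, distance=distance, prominence=min_prominence)
    valleys, _ = find_peaks(-x, distance=distance, prominence=min_prominence)
    peaks, valleys = _alternate(peaks, valleys, x)
    if peaks.size < 2 or valleys.size < 2:
        raise InsufficientCyclesError(
            f"found only {peaks.size} peaks / {valleys.size} valleys"
        )
    return peaks, valleys


def irregularity_value(
    peak_series: Sequence[float], valley_series: Sequence[float]
) -> float:
    """Mean of the population SDs of the peak and valley series."""
    p = np.asarray(peak_series, dtype=np.float64)
    v = np.asarray(valley_series, dtype=np.float64)
    if p.size < 2 or v.size < 2:
        raise InsufficientCyclesError("need >= 2 peaks and >= 2 valleys")
    return float((np.std(p) + np.std(v)) / 2.0)


def profile_signal(
    signal: RespirationSignal,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    min_prominence: float | None = None,
    detrend: bool = True,
) -> IrregularityProfile:
    """Detect extrema and compute both irregularity variants for one signal.

    Amplitude irregularity uses the extremum amplitudes; phase
    irregularity uses the peak-to-peak and valley-to-valley period series
    (seconds).  Linear detrending (default on) removes baseline drift
    first: a drifting baseline shifts every extremum in proportion to
    record length and would masquerade as breath-to-breath amplitude
    variability.
    """
    if detrend:
        signal = signal.with_samples(scipy_detrend(signal.samples, type="linear"))
    peaks, valleys = detect_extrema(signal, min_separation_s, min_prominence)
    t = signal.times
    x = signal.samples
    if peaks.size < 3 or valleys.size < 3:
        raise InsufficientCyclesError("need >= 3 peaks and valleys for period SDs")
    amp = irregularity_value(x[peaks], x[valleys])
    phase = irregularity_value(np.diff(t[peaks]), np.diff(t[valleys]))
    return IrregularityProfile(
        signal_id=signal.id,
        peak_times=t[peaks],
        peak_amplitudes=x[peaks],
        valley_times=t[valleys],
        valley_amplitudes=x[valleys],
        amplitude_irregularity=amp,
        phase_irregularity=phase,
        generating_group=signal.group,
    )


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = float(np.std(values))
    if sd == 0:
        return np.zeros_like(values)
    return (values - float(np.mean(values))) / sd


def classify_cohort(
    profiles: Sequence[IrregularityProfile],
    group_size: int,
    swap_type12: bool = False,
) -> list[IrregularityProfile]:
    """Assign four disjoint regularity groups of ``group_size`` each.

    Both irregularity axes are standardized within the cohort before
    ranking (amplitude z-units and period seconds are incommensurable and
    must not be summed raw).  Assignment order with exclusion: the
    ``group_size`` highest combined (sum of standardized axes) scores are
    ``type3``; of the rest, the highest phase scores are ``type1``, then
    the highest amplitude scores are ``type2``; the lowest combined scores
    are ``regular``.  Remaining signals stay unlabeled.  Ties break by
    signal id.  ``swap_type12`` exchanges the roles of the phase and
    amplitude axes for types 1 and 2.
    """
    if len(profiles) < 4 * group_size:
        raise InvalidCohortError(
            f"cohort of {len(profiles)} cannot form 4 groups of {group_size}"
        )
    profiles = list(profiles)
    amp = _standardize(np.array([p.amplitude_irregularity for p in profiles]))
    phase = _standardize(np.array([p.phase_irregularity for p in profiles]))
    combined = amp + phase
    for p, c in zip(profiles, combined):
        p.combined_irregularity = float(c)

    ids = [p.signal_id for p in profiles]

    def take(scores: np.ndarray, available: set[int], largest: bool) -> list[int]:
        ranked = sorted(
            available,
            key=lambda i: ((-scores[i]) if largest else scores[i], ids[i]),
        )
        return ranked[:group_size]

    available = set(range(len(profiles)))
    assignment: dict[int, str] = {}
    type1_axis, type2_axis = (amp, phase) if swap_type12 else (phase, amp)
    for label, scores, largest in (
        ("type3", combined, True),
        ("type1", type1_axis, True),
        ("type2", type2_axis, True),
        ("regular", combined, False),
    ):
        chosen = take(scores, available, largest)
        for i in chosen:
            assignment[i] = label
        available -= set(chosen)

    for i, p in enumerate(profiles):
        p.group = assignment.get(i)
    return profiles


def label_recovery_rate(profiles: Sequence[IrregularityProfile]) -> float:
    """Fraction of classified signals whose group matches the label their
    generator config carried (synthetic cohorts only)."""
    scored = [
        p for p in profiles if p.group is not None and p.generating_group is not None
    ]
    if not scored:
        raise InvalidCohortError("no labeled, classified profiles")
    hits = sum(p.group == p.generating_group for p in scored)
    return hits / len(scored)
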