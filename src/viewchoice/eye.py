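"""Synthetic 2-D gaze traces and velocity-threshold fixation detection.

A fixation is a maximal run of samples whose speed stays below 25% of the
trace's speed standard deviation for more than 60 ms.  Fixations beginning
within 100 ms of a stimulus onset are flagged as excluded (anticipatory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPEED_SD_FRACTION = 0.25
MIN_FIXATION_MS = 60.0
STIMULUS_EXCLUSION_MS = 100.0


@dataclass
class EyeTrace:
    """Uniformly sampled gaze positions (screen units)."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stimulus_onsets_ms: tuple[float, ...] = ()

    @property
    def fs_hz(self) -> float:
        return 1000.0 / float(self.t_ms[1] - self.t_ms[0])


@dataclass
class Fixation:
    onset_ms: float
    offset_ms: float
    region: str
    excluded: bool = False

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class FixationList:
    fixations: list[Fixation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)

    def included(self) -> list[Fixation]:
        return [f for f in self.fixations if not f.excluded]


#: canonical regions of interest (screen units)
ROIS = {"center": (0.0, 0.0), "left": (-10.0, 0.0), "right": (10.0, 0.0)}


def generate_eye_trace(dwells: list[tuple[str, float]], seed: int = 0,
                       fs_hz: float = 250.0, jitter_sd: float = 0.01,
                       saccade_ms: float = 30.0, quantum: float = 0.1,
                       stimulus_onsets_ms: tuple[float, ...] = ()) -> EyeTrace:
    """Gaze trace visiting ROIs: ``dwells`` is a list of (region, dwell_ms).

    Consecutive dwell points are joined by fast linear saccades; positions
    carry Gaussian jitter and are quantized to the tracker resolution
    ``quantum`` (so within-fixation samples are flat, as in real tracker
    output).  Sampling is uniform at ``fs_hz``.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / fs_hz
    xs, ys = [], []
    prev = None
    for region, dwell_ms in dwells:
        tx, ty = ROIS[region]
        if prev is not None:
            n_sac = max(int(saccade_ms / dt), 1)
            frac = np.linspace(0, 1, n_sac, endpoint=False)[1:]
            xs.extend(prev[0] + frac * (tx - prev[0]))
            ys.extend(prev[1] + frac * (ty - prev[1]))
        n_dwell = max(int(dwell_ms / dt), 1)
        xs.extend(np.full(n_dwell, tx))
        ys.extend(np.full(n_dwell, ty))
        prev = (tx, ty)
    x = np.asarray(xs) + rng.normal(0, jitter_sd, len(xs))
    y = np.asarray(ys) + rng.normal(0, jitter_sd, len(ys))
    if quantum > 0:
        x = np.round(x / quantum) * quantum
        y = np.round(y / quantum) * quantum
    t = np.arange(len(xs)) * dt
    return EyeTrace(t_ms=t, x=x, y=y, stimulus_onsets_ms=tuple(stimulus_onsets_ms))


def detect_fixations(trace: EyeTrace) -> FixationList:
    """Velocity-threshold fixation detection with anticipatory exclusion.

    Speed is computed by central differences; the threshold is 25% of the
    speed SD estimated from this trace.  Runs longer than 60 ms become
    fixations; a fixation starting within 100 ms after any stimulus onset is
    flagged ``excluded``.  Traces shorter than the minimum duration yield an
    empty list.
    """
    n = len(trace.t_ms)
    dt = float(trace.t_ms[1] - trace.t_ms[0]) if n > 1 else 0.0
    if n < 3 or (n - 1) * dt <= MIN_FIXATION_MS:
        return FixationList([])
    vx = np.gradient(trace.x, dt)
    vy = np.gradient(trace.y, dt)
    speed = np.hypot(vx, vy)
    thr = SPEED_SD_FRACTION * float(speed.std())
    # a motionless trace has zero speed SD; everything then counts as slow
    slow = speed < thr if thr > 0 else speed <= 0

    fixations: list[Fixation] = []
    i = 0
    while i < n:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j < n and slow[j]:
            j += 1
        onset, offset = trace.t_ms[i], trace.t_ms[min(j, n - 1)]
        if offset - onset > MIN_FIXATION_MS:
            cx, cy = trace.x[i:j].mean(), trace.y[i:j].mean()
            region = min(ROIS, key=lambda r: (ROIS[r][0] - cx) ** 2 + (ROIS[r][1] - cy) ** 2)
            excluded = any(0.0 <= onset - s0 < STIMULUS_EXCLUSION_MS
                           for s0 in trace.stimulus_onsets_ms)
            fixations.append(Fixation(float(onset), float(offset), region, excluded))
        i = j
    return FixationList(fixations)
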