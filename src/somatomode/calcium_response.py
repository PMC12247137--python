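"""ΔF/F0 analysis of in vivo DRG calcium recordings.

Converts raw per-neuron fluorescence into percent ΔF/F0 against a
stimulus-free baseline, calls per-stimulus activation with a peak
threshold (default ≥ 20 %), and summarizes responder overlap and
population amplitudes.

The two computational steps are exposed as sklearn-style estimators
(:class:`DeltaFOverF`, :class:`StimulusResponseCaller`) so they compose
in a :class:`sklearn.pipeline.Pipeline`; the module-level functions are
thin wrappers over them operating on the domain containers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Epoch",
    "FluorescenceRecording",
    "DffTrace",
    "ResponseCallTable",
    "OverlapSummary",
    "AmplitudeComparison",
    "DeltaFOverF",
    "StimulusResponseCaller",
    "compute_dff",
    "call_responses",
    "summarize_overlap",
    "activated_fraction",
    "population_mean_dff",
    "compare_amplitudes",
    "round_half_away",
]

EPOCH_KINDS = ("mechanical", "chemical")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (37.358 -> 37.4, -0.05 -> -0.1).

    Python's builtin ``round`` is banker's rounding; printed percentages in
    this pipeline use the half-away-from-zero convention instead.
    """
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class Epoch:
    """A stimulus presentation window.

    Parameters
    ----------
    label : str
        Stimulus name, e.g. ``"pinch"`` or ``"chloroquine"``.
    onset, offset : float
        Start/end of the stimulus in seconds from recording start. For
        chemical stimuli the onset is the injection time.
    kind : {"mechanical", "chemical"}
        Decides the analysis window used when calling responses.
    """

    label: str
    onset: float
    offset: float
    kind: str = "mechanical"

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"epoch kind must be one of {EPOCH_KINDS}, got {self.kind!r}")
        if not (0 <= self.onset < self.offset):
            raise ValueError(f"epoch needs 0 <= onset < offset, got ({self.onset}, {self.offset})")


@dataclass
class FluorescenceRecording:
    """Raw fluorescence traces (a.u.) for a field of view.

    ``traces`` is neurons x frames; all values must be strictly positive so
    F0 division is defined. Epoch onsets must be strictly increasing and lie
    inside the recording.
    """

    traces: np.ndarray
    frame_rate: float
    epochs: tuple[Epoch, ...]
    neuron_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D neurons x frames array")
        if not np.all(self.traces > 0):
            raise ValueError("all fluorescence values must be > 0 (F0 division)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.epochs = tuple(self.epochs)
        dur = self.duration
        onsets = [e.onset for e in self.epochs]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("epoch onsets must be strictly increasing")
        for e in self.epochs:
            if e.offset > dur + 1e-9:
                raise ValueError(f"epoch {e.label!r} extends past the recording end ({dur:.1f}s)")
        if not self.neuron_ids:
            self.neuron_ids = tuple(f"n{i:04d}" for i in range(self.traces.shape[0]))
        self.neuron_ids = tuple(self.neuron_ids)
        if len(self.neuron_ids) != self.traces.shape[0]:
            raise ValueError("neuron_ids length must match the number of trace rows")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def time(self) -> np.ndarray:
        """Frame times in seconds (frame i at i / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class DffTrace:
    """Percent ΔF/F0 traces with the per-neuron baseline F0 they came from."""

    dff: np.ndarray
    f0: np.ndarray
    frame_rate: float
    baseline_window: tuple[float, float]
    neuron_ids: tuple[str, ...]

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.dff.shape[1]) / self.frame_rate


class DeltaFOverF(BaseEstimator, TransformerMixin):
    """Baseline-normalizing transformer: F -> (F - F0)/F0 x 100 %.

    ``fit`` learns the per-neuron baseline F0 as the mean fluorescence over
    the first ``baseline_s`` seconds; ``transform`` maps every frame to
    percent ΔF/F0. Rows are neurons, columns are frames.
    """

    def __init__(self, frame_rate: float = 5.0, baseline_s: float = 60.0):
        self.frame_rate = frame_rate
        self.baseline_s = baseline_s

    def fit(self, X, y=None) -> "DeltaFOverF":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (neurons x frames)")
        k = int(round(self.baseline_s * self.frame_rate))
        if not 1 <= k <= X.shape[1]:
            raise ValueError(
                f"baseline window of {self.baseline_s}s needs {k} frames; recording has {X.shape[1]}"
            )
        f0 = X[:, :k].mean(axis=1)
        if np.any(f0 <= 0):
            raise ValueError("F0 must be positive for every neuron")
        self.f0_ = f0
        self.n_baseline_frames_ = k
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "f0_"):
            raise RuntimeError("DeltaFOverF must be fitted before transform")
        X = np.asarray(X, dtype=float)
        return (X - self.f0_[:, None]) / self.f0_[:, None] * 100.0


class StimulusResponseCaller(BaseEstimator):
    """Threshold classifier for per-epoch activation on ΔF/F0 traces.

    For each epoch an analysis window is fixed at ``fit`` time:

    * mechanical: onset to offset + ``mechanical_margin_s`` (decay margin);
    * chemical: onset + ``exclusion_s`` (injection-artifact exclusion) to
      onset + ``chemical_observation_s``.

    ``decision_function`` returns the peak ΔF/F0 inside each window;
    ``predict`` thresholds it (inclusive, default ≥ 20 %).
    """

    def __init__(
        self,
        epochs: Sequence[Epoch] = (),
        frame_rate: float = 5.0,
        threshold_pct: float = 20.0,
        exclusion_s: float = 60.0,
        mechanical_margin_s: float = 10.0,
        chemical_observation_s: float = 660.0,
    ):
        self.epochs = epochs
        self.frame_rate = frame_rate
        self.threshold_pct = threshold_pct
        self.exclusion_s = exclusion_s
        self.mechanical_margin_s = mechanical_margin_s
        self.chemical_observation_s = chemical_observation_s

    def _window(self, epoch: Epoch, duration: float) -> tuple[float, float]:
        if epoch.kind == "chemical":
            start = epoch.onset + self.exclusion_s
            end = min(epoch.onset + self.chemical_observation_s, duration)
        else:
            start = epoch.onset
            end = min(epoch.offset + self.mechanical_margin_s, duration)
        return start, end

    def fit(self, X, y=None) -> "StimulusResponseCaller":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (neurons x frames)")
        if not self.epochs:
            raise ValueError("at least one epoch is required")
        n_frames = X.shape[1]
        duration = n_frames / self.frame_rate
        t = np.arange(n_frames) / self.frame_rate
        windows, slices = [], []
        for e in self.epochs:
            start, end = self._window(e, duration)
            mask = (t >= start) & (t <= end)
            if start >= end or not mask.any():
                raise ValueError(
                    f"epoch {e.label!r}: analysis window [{start:.1f}, {end:.1f}]s is empty"
                )
            windows.append((start, end))
            slices.append(mask)
        self.windows_ = windows
        self.window_masks_ = slices
        self.n_frames_ = n_frames
        return self

    def decision_function(self, X) -> np.ndarray:
        """Peak ΔF/F0 (percent) per neuron per epoch, neurons x epochs."""
        if not hasattr(self, "window_masks_"):
            raise RuntimeError("StimulusResponseCaller must be fitted first")
        X = np.asarray(X, dtype=float)
        return np.column_stack([X[:, m].max(axis=1) for m in self.window_masks_])

    def predict(self, X) -> np.ndarray:
        """Boolean activation calls, neurons x epochs (peak ≥ threshold)."""
        return self.decision_function(X) >= self.threshold_pct


@dataclass
class ResponseCallTable:
    """Per (neuron, stimulus) activation calls with peak ΔF/F0.

    ``calls`` columns: neuron_id, stimulus, activated, peak_dff,
    window_start, window_end.
    """

    calls: pd.DataFrame
    threshold_pct: float

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.calls["stimulus"]))

    def activated_ids(self, stimulus: str) -> set[str]:
        if stimulus not in self.stimuli:
            raise KeyError(f"stimulus {stimulus!r} not present in call table")
        sub = self.calls[self.calls["stimulus"] == stimulus]
        return set(sub.loc[sub["activated"], "neuron_id"])

    def n_activated(self, stimulus: str) -> int:
        return len(self.activated_ids(stimulus))


@dataclass
class OverlapSummary:
    """Responder overlap between two stimuli (Euler-diagram arithmetic).

    Percentages use the union of responders as denominator and are rounded
    half-away-from-zero to one decimal. When the union is empty the counts
    are reported and ``defined`` is False (percentages are None).
    """

    stim_a: str
    stim_b: str
    n_both: int
    n_only_a: int
    n_only_b: int
    n_union: int
    pct_both: float | None
    pct_only_a: float | None
    pct_only_b: float | None
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "stim_a": self.stim_a,
            "stim_b": self.stim_b,
            "n_both": self.n_both,
            "n_only_a": self.n_only_a,
            "n_only_b": self.n_only_b,
            "n_union": self.n_union,
            "pct_both": self.pct_both,
            "pct_only_a": self.pct_only_a,
            "pct_only_b": self.pct_only_b,
            "defined": self.defined,
        }


@dataclass
class AmplitudeComparison:
    """Unpaired two-sample t test on peak ΔF/F0 amplitudes."""

    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    p: float
    stars: str
    equal_var: bool = True


def compute_dff(recording: FluorescenceRecording, baseline_s: float = 60.0) -> DffTrace:
    """Percent ΔF/F0 with F0 = mean fluorescence over the first ``baseline_s`` s.

    The baseline window must be stimulus-free: recordings whose first epoch
    starts before ``baseline_s`` are rejected rather than re-windowed.
    """
    for e in recording.epochs:
        if e.onset < baseline_s:
            raise ValueError(
                f"baseline window (first {baseline_s}s) overlaps epoch {e.label!r} at {e.onset}s"
            )
    est = DeltaFOverF(frame_rate=recording.frame_rate, baseline_s=baseline_s).fit(recording.traces)
    return DffTrace(
        dff=est.transform(recording.traces),
        f0=est.f0_,
        frame_rate=recording.frame_rate,
        baseline_window=(0.0, baseline_s),
        neuron_ids=recording.neuron_ids,
    )


def call_responses(
    dff: DffTrace,
    epochs: Sequence[Epoch],
    threshold_pct: float = 20.0,
    exclusion_s_after_injection: float = 60.0,
    mechanical_margin_s: float = 10.0,
    chemical_observation_s: float = 660.0,
) -> ResponseCallTable:
    """Call per-stimulus activation from peak ΔF/F0 in each analysis window.

    A neuron is activated by a stimulus iff its maximum ΔF/F0 inside the
    epoch's analysis window is ≥ ``threshold_pct`` (inclusive). For chemical
    epochs the first ``exclusion_s_after_injection`` seconds after injection
    are excluded and observation runs to ``chemical_observation_s`` after
    injection (default 11 min).
    """
    caller = StimulusResponseCaller(
        epochs=tuple(epochs),
        frame_rate=dff.frame_rate,
        threshold_pct=threshold_pct,
        exclusion_s=exclusion_s_after_injection,
        mechanical_margin_s=mechanical_margin_s,
        chemical_observation_s=chemical_observation_s,
    ).fit(dff.dff)
    peaks = caller.decision_function(dff.dff)
    active = caller.predict(dff.dff)
    rows = []
    for j, e in enumerate(epochs):
        start, end = caller.windows_[j]
        for i, nid in enumerate(dff.neuron_ids):
            rows.append(
                {
                    "neuron_id": nid,
                    "stimulus": e.label,
                    "activated": bool(active[i, j]),
                    "peak_dff": float(peaks[i, j]),
                    "window_start": start,
                    "window_end": end,
                }
            )
    return ResponseCallTable(calls=pd.DataFrame(rows), threshold_pct=threshold_pct)


def summarize_overlap(calls: ResponseCallTable, stim_a: str, stim_b: str) -> OverlapSummary:
    """Count neurons activated by both / only one of two stimuli.

    Percentages are over the union of responders, rounded half-away-from-zero
    to one decimal (so 198/530 prints as 37.4).
    """
    set_a = calls.activated_ids(stim_a)
    set_b = calls.activated_ids(stim_b)
    n_both = len(set_a & set_b)
    n_only_a = len(set_a - set_b)
    n_only_b = len(set_b - set_a)
    n_union = n_both + n_only_a + n_only_b
    if n_union == 0:
        return OverlapSummary(stim_a, stim_b, 0, 0, 0, 0, None, None, None, defined=False)
    return OverlapSummary(
        stim_a,
        stim_b,
        n_both,
        n_only_a,
        n_only_b,
        n_union,
        pct_both=round_half_away(100.0 * n_both / n_union),
        pct_only_a=round_half_away(100.0 * n_only_a / n_union),
        pct_only_b=round_half_away(100.0 * n_only_b / n_union),
    )


def activated_fraction(calls: ResponseCallTable, stimulus: str, n_detectable: int) -> float:
    """Percent of detectable neurons activated by a stimulus (1-dp rounding).

    ``n_detectable`` is an explicit input: the detectable population includes
    constitutively fluorescent neurons that never respond, so it cannot be
    derived from the call table.
    """
    if n_detectable <= 0:
        raise ValueError("n_detectable must be positive")
    n_act = calls.n_activated(stimulus)
    if n_act > n_detectable:
        raise ValueError(f"{n_act} activated neurons exceed n_detectable={n_detectable}")
    return round_half_away(100.0 * n_act / n_detectable)


def population_mean_dff(dff: DffTrace, neuron_ids: Iterable[str]) -> pd.DataFrame:
    """Per-frame mean and SEM of ΔF/F0 over a neuron subset.

    SEM uses ddof=1; for a single neuron it is undefined and reported as 0
    by convention.
    """
    ids = list(neuron_ids)
    if not ids:
        raise ValueError("neuron subset must be non-empty")
    index = {nid: i for i, nid in enumerate(dff.neuron_ids)}
    missing = [nid for nid in ids if nid not in index]
    if missing:
        raise KeyError(f"unknown neuron ids: {missing[:5]}")
    sub = dff.dff[[index[nid] for nid in ids], :]
    mean = sub.mean(axis=0)
    if sub.shape[0] > 1:
        sem = sub.std(axis=0, ddof=1) / np.sqrt(sub.shape[0])
    else:
        sem = np.zeros_like(mean)
    return pd.DataFrame({"time": dff.time, "mean_dff": mean, "sem_dff": sem})


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_amplitudes(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> AmplitudeComparison:
    """Two-sided unpaired t test on peak ΔF/F0 amplitudes (mean ± SEM).

    Student's pooled-variance test by default; pass ``equal_var=False`` for
    Welch's variant.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0  # degenerate zero-variance case: no evidence of a difference
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return AmplitudeComparison(
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_b=int(b.size),
        t=float(t),
        p=float(p),
        stars=_stars(float(p)),
        equal_var=equal_var,
    )
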