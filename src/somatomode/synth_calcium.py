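"""Synthetic stimulus-evoked GCaMP6s-like recordings with known responders.

Generates per-neuron fluorescence traces in which each neuron belongs to one
of four ground-truth classes with respect to a pain stimulus (A, e.g. pinch)
and an itch stimulus (B, e.g. brush): responds to both, only A, only B, or
neither. Responders carry calcium transients shaped by a double-exponential
kernel (fast rise, slow decay, approximating GCaMP6s kinetics) whose peak
ΔF/F0 equals the configured amplitude exactly in the noiseless limit;
multisensory ("both") neurons get larger default amplitudes than
single-sensory neurons. Chemical stimuli are modelled as a slow sustained
transient starting after the injection, optionally preceded by a brief
injection-artifact spike inside the first minute (to exercise the
post-injection exclusion rule downstream).

Additive i.i.d. Gaussian noise on fluorescence is the only noise source;
output is a pure function of the config, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calcium_response import Epoch, FluorescenceRecording

__all__ = [
    "CalciumSimConfig",
    "GroundTruthLabels",
    "generate_recording",
    "default_mechanical_epochs",
    "default_chemical_epochs",
]

RESPONDER_CLASSES = ("both", "only_a", "only_b", "none")

# Defaults anchored on the mechanical-overlap field of view: 198 both / 293
# pinch-only / 39 brush-only responders out of 1113 detectable neurons (so
# that pinch activates 44.1% of detectable neurons; the remaining 583 are
# constitutively fluorescent non-responders).
_DEFAULT_N = 1113
_DEFAULT_COUNTS = {"both": 198, "only_a": 293, "only_b": 39, "none": 583}


def default_mechanical_epochs() -> tuple[Epoch, ...]:
    """Two 10-s mechanical stimuli 5 min apart (pinch then brush)."""
    return (
        Epoch("pinch", 120.0, 130.0, "mechanical"),
        Epoch("brush", 420.0, 430.0, "mechanical"),
    )


def default_chemical_epochs() -> tuple[Epoch, ...]:
    """Two injections ≥ 40 min apart (chloroquine then formalin)."""
    return (
        Epoch("chloroquine", 120.0, 125.0, "chemical"),
        Epoch("formalin", 2520.0, 2525.0, "chemical"),
    )


@dataclass
class CalciumSimConfig:
    """Configuration for :func:`generate_recording`.

    Parameters
    ----------
    n_neurons : int
        Field-of-view size (detectable neurons).
    frame_rate : float
        Sampling rate in Hz.
    duration : float
        Recording length in seconds.
    baseline_level : float
        Baseline fluorescence in a.u. (> 0).
    noise_sd : float
        SD of additive Gaussian noise on fluorescence, a.u.
    epochs : tuple of Epoch
        Stimulus windows; the first onset must be ≥ 60 s so the baseline
        window is stimulus-free.
    stim_a, stim_b : str
        Labels of the two stimuli the responder classes refer to.
    class_fractions : mapping
        Fractions of {both, only_a, only_b, none}; must sum to 1.
        Ignored when ``class_counts`` is given.
    class_counts : mapping or None
        Exact per-class neuron counts (must sum to n_neurons). Takes
        precedence over ``class_fractions``.
    amplitude_dff : mapping (class, stimulus label) -> percent
        Target peak ΔF/F0 of the planted transient.
    kernel_rise_tau, kernel_decay_tau : float
        Double-exponential kernel time constants in seconds (mechanical).
    chem_rise_tau, chem_decay_tau, chem_response_delay_s : float
        Sustained-transient shape for chemical epochs; the response starts
        ``chem_response_delay_s`` after injection.
    injection_artifact_dff : float
        If > 0, a spike of this peak ΔF/F0 is added to every neuron 2 s
        after each chemical injection (inside the 1-min exclusion window).
    seed : int
        RNG seed; identical configs give bit-identical recordings.
    """

    n_neurons: int = _DEFAULT_N
    frame_rate: float = 5.0
    duration: float = 640.0
    baseline_level: float = 100.0
    noise_sd: float = 2.0
    epochs: tuple[Epoch, ...] = field(default_factory=default_mechanical_epochs)
    stim_a: str = "pinch"
    stim_b: str = "brush"
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {k: v / _DEFAULT_N for k, v in _DEFAULT_COUNTS.items()}
    )
    class_counts: Mapping[str, int] | None = None
    amplitude_dff: Mapping[tuple[str, str], float] = field(default_factory=dict)
    kernel_rise_tau: float = 0.2
    kernel_decay_tau: float = 1.5
    chem_rise_tau: float = 30.0
    chem_decay_tau: float = 240.0
    chem_response_delay_s: float = 90.0
    injection_artifact_dff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.amplitude_dff:
            # Multisensory neurons respond more strongly than single-sensory ones.
            self.amplitude_dff = {
                ("both", self.stim_a): 80.0,
                ("both", self.stim_b): 60.0,
                ("only_a", self.stim_a): 45.0,
                ("only_b", self.stim_b): 40.0,
            }
        self.validate()

    def validate(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("kernel_rise_tau", "kernel_decay_tau", "chem_rise_tau", "chem_decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kernel_rise_tau >= self.kernel_decay_tau:
            raise ValueError("kernel rise tau must be smaller than decay tau")
        if not self.epochs:
            raise ValueError("at least one epoch is required")
        if self.epochs[0].onset < 60.0:
            raise ValueError("first epoch onset must be >= 60 s (stimulus-free baseline)")
        for e in self.epochs:
            if e.offset > self.duration:
                raise ValueError(f"epoch {e.label!r} lies outside the recording")
        if self.class_counts is not None:
            missing = set(RESPONDER_CLASSES) - set(self.class_counts)
            if missing:
                raise ValueError(f"class_counts missing classes {sorted(missing)}")
            if any(v < 0 for v in self.class_counts.values()):
                raise ValueError("class_counts must be nonnegative")
            if sum(self.class_counts.values()) != self.n_neurons:
                raise ValueError("class_counts must sum to n_neurons")
        else:
            missing = set(RESPONDER_CLASSES) - set(self.class_fractions)
            if missing:
                raise ValueError(f"class_fractions missing classes {sorted(missing)}")
            total = sum(self.class_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class_fractions must sum to 1, got {total}")


@dataclass
class GroundTruthLabels:
    """Planted responder classes: one class per neuron.

    ``table`` columns: neuron_id, responder_class, responds_a, responds_b,
    amplitude_a, amplitude_b (planted peak ΔF/F0 in percent; 0 when the
    neuron does not respond to that stimulus).
    """

    table: pd.DataFrame
    stim_a: str
    stim_b: str

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.table["responder_class"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in RESPONDER_CLASSES}

    def ids_of_class(self, cls: str) -> set[str]:
        return set(self.table.loc[self.table["responder_class"] == cls, "neuron_id"])


def _class_counts(config: CalciumSimConfig) -> dict[str, int]:
    if config.class_counts is not None:
        return {c: int(config.class_counts[c]) for c in RESPONDER_CLASSES}
    # Largest-remainder apportionment so counts sum exactly to n_neurons.
    raw = {c: config.class_fractions[c] * config.n_neurons for c in RESPONDER_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = config.n_neurons - sum(counts.values())
    for c in sorted(RESPONDER_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _mech_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Double-exponential transient sampled on t >= 0, normalized to peak 1."""
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("kernel has no positive peak at this sampling rate")
    return k / peak


def _chem_shape(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Sustained chemical response sampled on t >= 0, normalized to peak 1."""
    s = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    peak = s.max()
    if peak <= 0:
        raise ValueError("chemical response shape has no positive peak")
    return s / peak


def generate_recording(
    config: CalciumSimConfig,
) -> tuple[FluorescenceRecording, GroundTruthLabels]:
    """Simulate a recording; returns the traces and the planted ground truth.

    Traces are ``baseline_level * (1 + dff_planted/100) + N(0, noise_sd)``
    where ``dff_planted`` is the sum of kernel-shaped transients scaled so
    that a planted responder's peak ΔF/F0 equals its configured amplitude
    exactly in the noiseless limit (kernels are normalized by their sampled
    maximum).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate

    counts = _class_counts(config)
    classes = np.repeat(
        [c for c in RESPONDER_CLASSES], [counts[c] for c in RESPONDER_CLASSES]
    )
    rng.shuffle(classes)
    neuron_ids = tuple(f"n{i:04d}" for i in range(config.n_neurons))

    responds = {
        "both": {config.stim_a, config.stim_b},
        "only_a": {config.stim_a},
        "only_b": {config.stim_b},
        "none": set(),
    }

    dff = np.zeros((config.n_neurons, n_frames))
    for epoch in config.epochs:
        onset_idx = np.searchsorted(t, epoch.onset)
        tail = t[onset_idx:] - t[onset_idx]
        if epoch.kind == "chemical":
            resp_idx = np.searchsorted(t, epoch.onset + config.chem_response_delay_s)
            resp_tail = t[resp_idx:] - t[resp_idx]
            shape = _chem_shape(resp_tail, config.chem_rise_tau, config.chem_decay_tau)
            start = resp_idx
        else:
            shape = _mech_kernel(tail, config.kernel_rise_tau, config.kernel_decay_tau)
            start = onset_idx
        for cls in RESPONDER_CLASSES:
            if epoch.label not in responds[cls]:
                continue
            amp = config.amplitude_dff.get((cls, epoch.label), 0.0)
            if amp == 0.0:
                continue
            rows = classes == cls
            dff[rows, start:] += amp * shape
        if epoch.kind == "chemical" and config.injection_artifact_dff > 0:
            art_idx = np.searchsorted(t, epoch.onset + 2.0)
            art_tail = t[art_idx:] - t[art_idx]
            artifact = config.injection_artifact_dff * _mech_kernel(
                art_tail, config.kernel_rise_tau, config.kernel_decay_tau
            )
            dff[:, art_idx:] += artifact

    traces = config.baseline_level * (1.0 + dff / 100.0)
    if config.noise_sd > 0:
        traces = traces + rng.normal(0.0, config.noise_sd, traces.shape)
    # Fluorescence must stay positive for F0 division; with realistic noise
    # levels this clip never engages.
    traces = np.maximum(traces, 1e-9)

    amp_a = np.array(
        [config.amplitude_dff.get((c, config.stim_a), 0.0) if config.stim_a in responds[c] else 0.0 for c in classes]
    )
    amp_b = np.array(
        [config.amplitude_dff.get((c, config.stim_b), 0.0) if config.stim_b in responds[c] else 0.0 for c in classes]
    )
    truth = GroundTruthLabels(
        table=pd.DataFrame(
            {
                "neuron_id": neuron_ids,
                "responder_class": classes,
                "responds_a": [config.stim_a in responds[c] for c in classes],
                "responds_b": [config.stim_b in responds[c] for c in classes],
                "amplitude_a": amp_a,
                "amplitude_b": amp_b,
            }
        ),
        stim_a=config.stim_a,
        stim_b=config.stim_b,
    )
    rec = FluorescenceRecording(
        traces=traces,
        frame_rate=config.frame_rate,
        epochs=config.epochs,
        neuron_ids=neuron_ids,
    )
    return rec, truth
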