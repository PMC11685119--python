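"""Synthetic multi-subject EEG cohort with known class and subject structure.

Emulates the shape of a 62-channel, 200 Hz emotion-recognition cohort:
each trial is a sum of band-limited Gaussian noise processes, one per
canonical frequency band, whose per-channel amplitudes carry the class
signal, plus broadband sensor noise and a per-subject domain shift.

Two independent class effects are modelled:

* amplitude effects — a class multiplies the band amplitude on all channels
  of a scalp region (frontal / central / posterior row bands of the layout);
  a multiplier m shifts that band's differential entropy by exactly ln(m);
* topology effects — a class adds a shared band-limited component to chosen
  electrode pairs, creating inter-channel correlation (and an amplitude
  bump) at specific sites.

The domain shift has three per-subject parts: a per-channel multiplicative
gain (log-normal), a per-band multiplicative spectral tilt (log-normal,
shared by all channels), and a DC offset. The channel gain moves every
band's DE of that channel by ln(gain); the band tilt moves one band's DE of
every channel by ln(tilt) — the classic inter-subject band-power
variability that breaks pooled cross-subject classifiers and that the
adversarial branch is meant to absorb; the offset is removed by band-pass
filtering and is present only to exercise preprocessing.

All draws descend from ``CohortSpec.seed`` through named
``numpy.random.SeedSequence`` children, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .layout_features import BandScheme, ElectrodeLayout, RawRecording

__all__ = ["CohortSpec", "GroundTruth", "generate_trial", "generate_cohort", "region_of"]

# base per-band component amplitudes (arbitrary microvolt-ish scale)
BASE_AMPLITUDE = {"delta": 10.0, "theta": 8.0, "alpha": 8.0, "beta": 6.0, "gamma": 4.0}

# class -> {(band, region): amplitude multiplier}
DEFAULT_CLASS_EFFECTS: dict[int, dict[tuple[str, str], float]] = {
    0: {},
    1: {("alpha", "posterior"): 2.0, ("theta", "frontal"): 1.5},
    2: {("beta", "frontal"): 2.0, ("gamma", "frontal"): 1.5},
    3: {("theta", "central"): 2.0, ("alpha", "frontal"): 0.5},
}

# class -> [(electrode_a, electrode_b, band, relative amplitude)]
DEFAULT_TOPOLOGY_EFFECTS: dict[int, list[tuple[str, str, str, float]]] = {
    0: [],
    1: [("FP1", "O1", "beta", 1.0), ("FP2", "O2", "beta", 1.0)],
    2: [("F3", "P3", "gamma", 1.0), ("F4", "P4", "gamma", 1.0)],
    3: [("C3", "C4", "alpha", 1.0)],
}


def region_of(layout: ElectrodeLayout, electrode_index: int) -> str:
    """Coarse scalp region from the grid row (frontal rows 0-2, central 3-5,
    posterior 6-8)."""
    row = layout.grid_coords[electrode_index][0]
    third = layout.height / 3.0
    if row < third:
        return "frontal"
    if row < 2 * third:
        return "central"
    return "posterior"


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of the synthetic cohort."""

    n_subjects: int = 15
    n_classes: int = 3
    trials_per_subject_per_class: int = 3
    fs: float = 200.0
    trial_seconds: float = 60.0
    class_effects: dict | None = None
    topology_effects: dict | None = None
    class_effect_on: bool = True
    topology_effect_on: bool = True
    subject_gain_log_sd: float = 0.4
    subject_band_log_sd: float = 0.4
    subject_offset_sd: float = 5.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (3, 4):
            raise ValueError("n_classes must be 3 or 4")
        if self.fs * self.trial_seconds < 4 * self.fs:
            raise ValueError("a trial must span at least one 4-s window")

    def effects(self) -> dict[int, dict[tuple[str, str], float]]:
        if not self.class_effect_on:
            return {k: {} for k in range(self.n_classes)}
        src = self.class_effects or DEFAULT_CLASS_EFFECTS
        eff = {k: dict(src.get(k, {})) for k in range(self.n_classes)}
        for mults in eff.values():
            if any(m <= 0 for m in mults.values()):
                raise ValueError("amplitude multipliers must be > 0")
        return eff

    def topo_effects(self) -> dict[int, list]:
        if not self.topology_effect_on:
            return {k: [] for k in range(self.n_classes)}
        src = self.topology_effects or DEFAULT_TOPOLOGY_EFFECTS
        return {k: list(src.get(k, [])) for k in range(self.n_classes)}


@dataclass
class GroundTruth:
    """What was actually drawn: trial registry and per-subject shifts."""

    trials: list[dict] = field(default_factory=list)
    subject_gains: dict[str, list[float]] = field(default_factory=dict)
    subject_band_tilts: dict[str, list[float]] = field(default_factory=dict)
    subject_offsets: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "trials": self.trials,
                "subject_gains": self.subject_gains,
                "subject_band_tilts": self.subject_band_tilts,
                "subject_offsets": self.subject_offsets,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(trials=d["trials"], subject_gains=d["subject_gains"],
                   subject_band_tilts=d.get("subject_band_tilts", {}),
                   subject_offsets=d["subject_offsets"])


def _band_noise(rng: np.random.Generator, shape, lo: float, hi: float,
                fs: float) -> np.ndarray:
    """Unit-variance-ish band-limited Gaussian noise (zero-phase filtered)."""
    sos = signal.butter(5, [lo, hi], btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal(shape)
    band = signal.sosfiltfilt(sos, white, axis=-1)
    # renormalise so the stated amplitudes are the realised standard deviations
    sd = band.std(axis=-1, keepdims=True)
    return band / np.where(sd > 0, sd, 1.0)


def subject_shift(
    spec: CohortSpec, subject: int, layout: ElectrodeLayout, n_bands: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel gain, per-band tilt and offset of one subject
    (deterministic in the cohort seed)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 1000 + subject])
    )
    gains = np.exp(rng.normal(0.0, spec.subject_gain_log_sd, size=len(layout)))
    band_tilts = np.exp(rng.normal(0.0, spec.subject_band_log_sd, size=n_bands))
    offsets = rng.normal(0.0, spec.subject_offset_sd, size=len(layout))
    return gains, band_tilts, offsets


def generate_trial(
    spec: CohortSpec,
    subject: int,
    klass: int,
    rng: np.random.Generator,
    layout: ElectrodeLayout | None = None,
    scheme: BandScheme | None = None,
    trial_id: str = "",
) -> RawRecording:
    """One trial: channels x samples with the class/subject structure above."""
    layout = layout or ElectrodeLayout.default()
    scheme = scheme or BandScheme()
    n = int(round(spec.fs * spec.trial_seconds))
    ne = len(layout)
    regions = [region_of(layout, e) for e in range(ne)]
    effects = spec.effects()[klass]
    gains, band_tilts, offsets = subject_shift(spec, subject, layout, len(scheme))
    x = np.zeros((ne, n))
    for b, (name, lo, hi) in enumerate(scheme.bands):
        base = BASE_AMPLITUDE[name] * band_tilts[b]
        amp = np.array([
            base * effects.get((name, regions[e]), 1.0) for e in range(ne)
        ])
        x += amp[:, None] * _band_noise(rng, (ne, n), lo, hi, spec.fs)
    band_lookup = {b[0]: (i, *b[1:]) for i, b in enumerate(scheme.bands)}
    for ch_a, ch_b, band, rel in spec.topo_effects()[klass]:
        b, lo, hi = band_lookup[band]
        shared = (BASE_AMPLITUDE[band] * band_tilts[b] * rel
                  * _band_noise(rng, (n,), lo, hi, spec.fs))
        x[layout.index_of(ch_a)] += shared
        x[layout.index_of(ch_b)] += shared
    x += spec.noise_sd * rng.standard_normal((ne, n))
    x = x * gains[:, None] + offsets[:, None]
    return RawRecording(
        samples=x,
        fs=spec.fs,
        channel_names=list(layout.names),
        subject_id=f"S{subject:02d}",
        trial_id=trial_id,
        label=klass,
    )


def generate_cohort(
    spec: CohortSpec,
    layout: ElectrodeLayout | None = None,
    scheme: BandScheme | None = None,
) -> tuple[list[RawRecording], GroundTruth]:
    """Full factorial subjects x classes x trials, plus the ground truth."""
    layout = layout or ElectrodeLayout.default()
    scheme = scheme or BandScheme()
    truth = GroundTruth()
    recordings = []
    for s in range(spec.n_subjects):
        gains, band_tilts, offsets = subject_shift(spec, s, layout, len(scheme))
        sid = f"S{s:02d}"
        truth.subject_gains[sid] = gains.tolist()
        truth.subject_band_tilts[sid] = band_tilts.tolist()
        truth.subject_offsets[sid] = offsets.tolist()
        for k in range(spec.n_classes):
            for t in range(spec.trials_per_subject_per_class):
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, s, k, t])
                )
                trial_id = f"{sid}_c{k}_t{t}"
                rec = generate_trial(spec, s, k, rng, layout, scheme, trial_id)
                recordings.append(rec)
                truth.trials.append(
                    {"trial_id": trial_id, "subject": sid, "class": k}
                )
    return recordings, truth
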