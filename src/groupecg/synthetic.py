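"""Seeded synthetic multi-lead ECG generator with class-conditional morphology.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) — the standard
synthetic-ECG construction — projected onto the requested leads through a
per-lead amplitude table.  Disease classes perturb the morphology on the
leads where the corresponding clinical pattern shows up:

* infarctions shift the ST segment on their territory leads
  (anterior → V1–V4, inferior → II/III/aVF, lateral → I/aVL/V5/V6);
* ventricular hypertrophy scales the R amplitude (left → V5/V6/I,
  right → V1/V2);
* atrial hypertrophy widens (left) or peaks (right) the P wave;
* rhythm classes act on the RR sequence (sinus arrhythmia → high RR
  variance, heart block → dropped QRS complexes, atrial/ventricular
  arrhythmia → ectopic beats, junctional → absent P).

Everything is driven by explicit numpy generators: the same seed and
parameters always give bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ECGRecord, LabelPair
from .taxonomy import (
    InvalidLabelError,
    STANDARD_LEADS,
    TASK2_CLASSES,
    clinical_priors,
    map_task2_to_task1,
)

__all__ = [
    "BeatMorphology", "LeadProjection", "ClassEffect", "NoiseParams",
    "default_morphology", "default_projection", "class_effects",
    "generate_beat", "generate_record", "generate_dataset", "st_window",
]

WAVES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class BeatMorphology:
    """P-QRS-T beat shape: per-wave center (s), amplitude (mV) and width (s)."""

    wave_centers: tuple[float, float, float, float, float]
    wave_amplitudes: tuple[float, float, float, float, float]
    wave_widths: tuple[float, float, float, float, float]
    pr_interval: float
    st_offset: float = 0.0

    def __post_init__(self):
        if any(w <= 0 for w in self.wave_widths):
            raise ValueError("wave widths must be positive")
        if not all(a < b for a, b in zip(self.wave_centers, self.wave_centers[1:])):
            raise ValueError("wave centers must be strictly increasing P<Q<R<S<T")
        if self.pr_interval <= 0:
            raise ValueError("pr_interval must be positive")


def default_morphology() -> BeatMorphology:
    """A normal-rhythm beat; values are in the physiological ballpark."""
    return BeatMorphology(
        wave_centers=(0.10, 0.21, 0.24, 0.27, 0.45),
        wave_amplitudes=(0.15, -0.10, 1.00, -0.25, 0.35),
        wave_widths=(0.025, 0.010, 0.012, 0.012, 0.055),
        pr_interval=0.14,
    )


def st_window(morph: BeatMorphology) -> tuple[float, float]:
    """The ST segment: from the end of the S wave to the onset of the T wave."""
    s_end = morph.wave_centers[3] + 3.0 * morph.wave_widths[3]
    t_start = morph.wave_centers[4] - 2.0 * morph.wave_widths[4]
    return s_end, max(t_start, s_end + 0.01)


@dataclass(frozen=True)
class LeadProjection:
    """Per-lead amplitude multipliers for the five waves."""

    weights: np.ndarray                  # [n_leads, 5]
    lead_names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=np.float64))
        object.__setattr__(self, "lead_names", tuple(self.lead_names))
        if len(self.lead_names) < 2:
            raise ValueError("at least 2 leads required")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if self.weights.shape != (len(self.lead_names), len(WAVES)):
            raise ValueError("weights must be [n_leads x 5]")

    def subset(self, lead_names: Sequence[str]) -> "LeadProjection":
        rows = [self.lead_names.index(name) for name in lead_names]
        return LeadProjection(self.weights[rows], tuple(lead_names))


#: Stylized projection of the five waves onto the 12 standard leads
#: (aVR inverted, precordial R-wave progression V1→V6).
_PROJECTION_TABLE: dict[str, tuple[float, float, float, float, float]] = {
    #        P     Q     R     S     T
    "I":   (0.8,  0.5,  0.7,  0.3,  0.7),
    "II":  (1.0,  0.8,  1.0,  0.5,  1.0),
    "III": (0.5,  0.6,  0.5,  0.4,  0.4),
    "aVR": (-0.9, -0.6, -0.9, -0.4, -0.9),
    "aVL": (0.3,  0.3,  0.4,  0.3,  0.3),
    "aVF": (0.8,  0.7,  0.8,  0.5,  0.7),
    "V1":  (0.3,  0.2, -0.3,  1.3, -0.3),
    "V2":  (0.4,  0.2,  0.2,  1.4,  0.6),
    "V3":  (0.5,  0.3,  0.5,  1.1,  0.8),
    "V4":  (0.6,  0.4,  0.9,  0.8,  0.9),
    "V5":  (0.7,  0.5,  1.1,  0.5,  0.9),
    "V6":  (0.7,  0.5,  1.0,  0.4,  0.8),
}


def default_projection(lead_names: Sequence[str] = STANDARD_LEADS) -> LeadProjection:
    unknown = [l for l in lead_names if l not in _PROJECTION_TABLE]
    if unknown:
        raise ValueError(f"unknown leads: {unknown}")
    return LeadProjection(
        np.array([_PROJECTION_TABLE[l] for l in lead_names]), tuple(lead_names))


@dataclass(frozen=True)
class ClassEffect:
    """How one fine-task class perturbs rhythm and morphology.

    ``morphology_deltas`` maps a wave name to per-wave modifications
    (``amp_scale``, ``amp_shift``, ``width_scale``, ``center_shift``);
    ``st_delta`` shifts the ST baseline (mV) on ``affected_leads``.
    """

    label2: str
    rr_mean: float = 0.8
    rr_sd: float = 0.03
    affected_leads: tuple[str, ...] = ()
    morphology_deltas: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    st_delta: float = 0.0
    ectopic_rate: float = 0.0
    dropped_beat_rate: float = 0.0

    def __post_init__(self):
        if self.label2 not in TASK2_CLASSES:
            raise InvalidLabelError(f"unknown fine label {self.label2!r}")
        if self.rr_mean <= 0:
            raise ValueError("rr_mean must be positive")
        for rate in (self.ectopic_rate, self.dropped_beat_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def class_effects() -> dict[str, ClassEffect]:
    """Default effect table for all 15 fine-task classes."""
    left_v, right_v = ("I", "V5", "V6"), ("V1", "V2")
    atrial = ("II", "III", "aVF", "V1")
    return {e.label2: e for e in [
        ClassEffect("N"),
        ClassEffect("SA", rr_sd=0.18),
        ClassEffect("AA", ectopic_rate=0.35, rr_sd=0.08,
                    affected_leads=("II", "III", "aVF"),
                    morphology_deltas={"P": {"amp_scale": 0.4}}),
        ClassEffect("JA", rr_mean=0.95,
                    affected_leads=("II", "III", "aVF"),
                    morphology_deltas={"P": {"amp_scale": -0.6}}),
        ClassEffect("VA", ectopic_rate=0.25,
                    affected_leads=STANDARD_LEADS,
                    morphology_deltas={"R": {"width_scale": 2.5}}),
        ClassEffect("HB", dropped_beat_rate=0.3, rr_mean=0.9,
                    affected_leads=("II",),
                    morphology_deltas={"P": {"center_shift": -0.03}}),
        ClassEffect("AMI", affected_leads=("V1", "V2", "V3", "V4"), st_delta=0.25,
                    morphology_deltas={"Q": {"amp_scale": 2.5}}),
        ClassEffect("IMI", affected_leads=("II", "III", "aVF"), st_delta=0.25,
                    morphology_deltas={"Q": {"amp_scale": 2.5}}),
        ClassEffect("LMI", affected_leads=("I", "aVL", "V5", "V6"), st_delta=0.25,
                    morphology_deltas={"Q": {"amp_scale": 2.5}}),
        ClassEffect("LVH", affected_leads=left_v,
                    morphology_deltas={"R": {"amp_scale": 1.9}}),
        ClassEffect("RVH", affected_leads=right_v,
                    morphology_deltas={"R": {"amp_scale": 1.9}, "S": {"amp_scale": 1.6}}),
        ClassEffect("BVH", affected_leads=left_v + right_v,
                    morphology_deltas={"R": {"amp_scale": 1.9}}),
        ClassEffect("LAH", affected_leads=atrial,
                    morphology_deltas={"P": {"width_scale": 2.0}}),
        ClassEffect("RAH", affected_leads=atrial,
                    morphology_deltas={"P": {"amp_scale": 2.2}}),
        ClassEffect("BAH", affected_leads=atrial,
                    morphology_deltas={"P": {"width_scale": 1.8, "amp_scale": 1.8}}),
    ]}


def apply_deltas(morph: BeatMorphology,
                 deltas: Mapping[str, Mapping[str, float]],
                 st_delta: float = 0.0) -> BeatMorphology:
    centers = list(morph.wave_centers)
    amps = list(morph.wave_amplitudes)
    widths = list(morph.wave_widths)
    for wave, mods in deltas.items():
        i = WAVES.index(wave)
        amps[i] = amps[i] * mods.get("amp_scale", 1.0) + mods.get("amp_shift", 0.0)
        widths[i] = widths[i] * mods.get("width_scale", 1.0)
        centers[i] = centers[i] + mods.get("center_shift", 0.0)
    return replace(morph, wave_centers=tuple(centers), wave_amplitudes=tuple(amps),
                   wave_widths=tuple(widths), st_offset=morph.st_offset + st_delta)


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise: white Gaussian plus low-frequency baseline wander."""

    gaussian_sd: float = 0.02        # mV
    baseline_amp: float = 0.05       # mV
    baseline_freq: float = 0.33      # Hz (respiratory range)
    powerline_amp: float = 0.0       # mV, off by default
    powerline_freq: float = 50.0     # Hz


# -- waveform synthesis --------------------------------------------------------

def _wave_basis(morph: BeatMorphology, fs: float, rr: float) -> np.ndarray:
    """Unit-amplitude Gaussian bumps for the five waves: [5, round(rr*fs)]."""
    n = int(round(rr * fs))
    t = np.arange(n) / fs
    centers = np.asarray(morph.wave_centers)[:, None]
    widths = np.asarray(morph.wave_widths)[:, None]
    return np.exp(-0.5 * ((t[None, :] - centers) / widths) ** 2)


def _st_mask(morph: BeatMorphology, fs: float, n: int) -> np.ndarray:
    t0, t1 = st_window(morph)
    t = np.arange(n) / fs
    return ((t >= t0) & (t < t1)).astype(np.float64)


def generate_beat(morph: BeatMorphology, fs: float, rr: float) -> np.ndarray:
    """One single-lead beat of ``round(rr*fs)`` samples."""
    if fs <= 0 or rr <= 0:
        raise ValueError("fs and rr must be positive")
    basis = _wave_basis(morph, fs, rr)
    beat = np.asarray(morph.wave_amplitudes) @ basis
    if morph.st_offset != 0.0:
        beat = beat + morph.st_offset * _st_mask(morph, fs, basis.shape[1])
    return beat


def generate_record(label2: str, duration: float = 10.0, fs: float = 500.0,
                    projection: LeadProjection | None = None,
                    effect: ClassEffect | None = None,
                    noise: NoiseParams | None = None,
                    seed: int | None = None,
                    record_id: str | None = None) -> ECGRecord:
    """Generate one multi-lead record for a fine-task class.

    The beat train is built at the class's RR statistics; class morphology
    changes apply only on ``effect.affected_leads``.  ``seed`` is required
    — generation is fully deterministic given (seed, parameters).
    """
    if label2 not in TASK2_CLASSES:
        raise InvalidLabelError(f"unknown fine label {label2!r}")
    if seed is None:
        raise ValueError("seed is required for reproducible generation")
    effect = effect if effect is not None else class_effects()[label2]
    projection = projection if projection is not None else default_projection()
    noise = noise if noise is not None else NoiseParams()
    if duration < 2 * effect.rr_mean:
        raise ValueError("duration must cover at least two beats")

    rng = np.random.default_rng(seed)
    n_total = int(round(duration * fs))
    base = default_morphology()
    affected = apply_deltas(base, effect.morphology_deltas, effect.st_delta)
    affected_mask = np.array([name in effect.affected_leads
                              for name in projection.lead_names])

    signal = np.zeros((len(projection.lead_names), n_total))
    pos = 0
    while pos < n_total:
        rr = float(np.clip(rng.normal(effect.rr_mean, effect.rr_sd), 0.4, 2.0))
        base_b, affected_b = base, affected
        if effect.dropped_beat_rate and rng.random() < effect.dropped_beat_rate:
            # blocked beat: P wave present, QRS and T suppressed, pause follows
            drop = {w: {"amp_scale": 0.0} for w in ("Q", "R", "S", "T")}
            base_b = apply_deltas(base_b, drop)
            affected_b = apply_deltas(affected_b, drop)
            rr *= 1.8
        elif effect.ectopic_rate and rng.random() < effect.ectopic_rate:
            ect = {"P": {"amp_scale": 0.0},
                   "R": {"width_scale": 2.5, "amp_scale": 1.2}}
            base_b = apply_deltas(base_b, ect)
            affected_b = apply_deltas(affected_b, ect)
            rr *= 0.7
        for morph, mask in ((base_b, ~affected_mask), (affected_b, affected_mask)):
            if not mask.any():
                continue
            basis = _wave_basis(morph, fs, rr)
            n_beat = basis.shape[1]
            amps = projection.weights[mask] * np.asarray(morph.wave_amplitudes)
            chunk = amps @ basis                      # [n_sel, n_beat]
            if morph.st_offset != 0.0:
                chunk = chunk + morph.st_offset * _st_mask(morph, fs, n_beat)
            end = min(pos + n_beat, n_total)
            signal[mask, pos:end] += chunk[:, :end - pos]
        pos += basis.shape[1]

    if noise.gaussian_sd > 0:
        signal += rng.normal(0.0, noise.gaussian_sd, size=signal.shape)
    if noise.baseline_amp > 0:
        t = np.arange(n_total) / fs
        phase = rng.uniform(0, 2 * np.pi)
        signal += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + phase)[None, :]
    if noise.powerline_amp > 0:
        t = np.arange(n_total) / fs
        signal += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t)[None, :]

    return ECGRecord(
        signal=signal, fs=fs, lead_names=projection.lead_names,
        labels=LabelPair.from_task2(label2),
        record_id=record_id or f"{label2}-{seed}", seed=seed)


def _record_seed(master_seed: int, index: int) -> int:
    """Deterministic, order-independent per-record seed from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(n_records: int,
                     class_priors: np.ndarray | None = None,
                     duration: float = 10.0, fs: float = 500.0,
                     lead_names: Sequence[str] = STANDARD_LEADS,
                     seed: int = 0,
                     noise: NoiseParams | None = None,
                     effects: Mapping[str, ClassEffect] | None = None,
                     ) -> tuple[list[ECGRecord], pd.DataFrame]:
    """Generate a labeled dataset plus its manifest.

    Labels are drawn from ``class_priors`` over the 15 fine classes
    (default: the clinical-corpus prior with 61.10% normal rhythm).  Each
    record's seed derives from (master seed, record index), so record i is
    identical no matter how many records are requested.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    priors = clinical_priors() if class_priors is None else np.asarray(class_priors, float)
    if priors.shape != (len(TASK2_CLASSES),):
        raise ValueError(f"class_priors must have length {len(TASK2_CLASSES)}")
    if (priors < 0).any():
        raise ValueError("class priors must be nonnegative")
    if not np.isclose(priors.sum(), 1.0, atol=1e-6):
        raise ValueError("class priors must sum to 1")
    priors = priors / priors.sum()
    effects = dict(effects) if effects is not None else class_effects()
    projection = default_projection(lead_names)

    records: list[ECGRecord] = []
    rows = []
    cum = np.cumsum(priors)
    for i in range(n_records):
        rec_seed = _record_seed(seed, i)
        label_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i, 1)))
        label2 = TASK2_CLASSES[int(np.searchsorted(cum, label_rng.random()))]
        rec = generate_record(
            label2, duration=duration, fs=fs, projection=projection,
            effect=effects[label2], noise=noise, seed=rec_seed,
            record_id=f"rec{i:05d}")
        records.append(rec)
        rows.append({"record_id": rec.record_id, "task1": rec.labels.task1,
                     "task2": label2, "seed": rec_seed})
    return records, pd.DataFrame(rows)
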