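"""Synthetic cohorts with known ground truth.

Generates everything the analysis consumes: per-neuron fluorescence traces
(Poisson transient trains rendered through the rise-decay kernel, plus slow
drift and Gaussian noise), centroid tracks whose speed can be coupled to
transient times, two-channel photometry with a shared artifact and an
additive dopamine response, and multi-animal multi-session cohorts with a
cross-session identity map.

Transient trains are homogeneous Poisson within each recording window, at
``rate_pre_hz`` before the injection and ``rate_post_hz`` after.  The true
inter-transient-interval distribution of striatal neurons is unknown; Poisson
is a modelling choice that satisfies the exchangeable-interval assumption the
shuffling null relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignError, SessionDesign
from .movement import VelocityTrace
from .photometry import PhotometrySignal
from .transients import (
    RawTrace,
    TransientModelParams,
    TransientTrain,
    eval_kernel,
    kernel_onset,
)

__all__ = [
    "SynthNeuronSpec",
    "SynthGroundTruth",
    "SynthConfig",
    "gen_event_train",
    "render_trace",
    "gen_velocity",
    "velocity_to_centroid",
    "gen_photometry",
    "gen_cohort",
]

#: default transient shape: ~0.15 s time-to-peak, ~0.8 s decay (GCaMP6f-like)
DEFAULT_SHAPE = TransientModelParams(alpha_p=2.0, tau_g=0.06, tau_d=0.8, t0=0.0)


@dataclass
class SynthNeuronSpec:
    """Generating parameters and true label of one synthetic neuron."""

    neuron_id: str
    class_tag: str = "D1-like"            # or "D2-like"
    rate_pre_hz: float = 0.1
    rate_post_hz: float = 0.1
    true_label: str = "none"              # elevated / reduced / none
    shape: TransientModelParams = DEFAULT_SHAPE
    noise_sd: float = 0.15
    drift_amp: float = 0.0
    drift_period_s: float = 120.0
    velocity_coupling: str = "none"       # heightened / lowered / none
    coupling_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_pre_hz < 0 or self.rate_post_hz < 0:
            raise ValueError("rates must be nonnegative")
        if self.true_label == "elevated" and not self.rate_post_hz > self.rate_pre_hz:
            raise ValueError("elevated label requires rate_post > rate_pre")
        if self.true_label == "reduced" and not self.rate_post_hz < self.rate_pre_hz:
            raise ValueError("reduced label requires rate_post < rate_pre")
        if self.class_tag not in ("D1-like", "D2-like"):
            raise ValueError("class_tag must be D1-like or D2-like")


@dataclass
class SynthGroundTruth:
    """Everything needed to score recovery of a synthetic cohort."""

    seed: int
    specs: dict = field(default_factory=dict)         # (animal, session, neuron) keyed
    event_t0s: dict = field(default_factory=dict)     # kernel t0 times per neuron
    event_onsets: dict = field(default_factory=dict)  # half-rise times per neuron

    def to_json(self, path: str | Path) -> None:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (TransientModelParams,)):
                return asdict(v)
            if isinstance(v, SynthNeuronSpec):
                d = asdict(v)
                return d
            return v

        payload = {
            "seed": self.seed,
            "specs": {k: enc(v) for k, v in self.specs.items()},
            "event_t0s": {k: enc(v) for k, v in self.event_t0s.items()},
            "event_onsets": {k: enc(v) for k, v in self.event_onsets.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# event trains and traces


def gen_event_train(
    spec: SynthNeuronSpec, design: SessionDesign, seed: int | np.random.Generator
) -> TransientTrain:
    """Homogeneous Poisson train: ``rate_pre_hz`` in windows ending at or
    before the injection, ``rate_post_hz`` afterwards.  Deterministic given
    the seed."""
    rng = np.random.default_rng(seed)
    times = []
    for a, b in design.windows:
        rate = spec.rate_pre_hz if b <= design.injection_time_s else spec.rate_post_hz
        n = rng.poisson(rate * (b - a))
        times.append(np.sort(rng.uniform(a, b, size=n)))
    onsets = np.concatenate(times)
    # de-duplicate pathological coincidences so onsets are strictly increasing
    while np.any(np.diff(onsets) <= 0):
        keep = np.concatenate([[True], np.diff(onsets) > 0])
        onsets = onsets[keep]
    return TransientTrain(
        neuron_id=spec.neuron_id, session_id=design.session_id, onsets_s=onsets
    )


def render_trace(
    train: TransientTrain,
    spec: SynthNeuronSpec,
    design: SessionDesign,
    seed: int | np.random.Generator,
) -> RawTrace:
    """Render a fluorescence trace: one kernel per event (the event time is
    the kernel ``t0``), plus a slow sinusoidal drift and i.i.d. Gaussian
    noise, sampled on the recorded frame grid."""
    spec.shape.validate()
    rng = np.random.default_rng(seed)
    t = design.frame_times()
    y = np.zeros_like(t)
    support = 10.0 * spec.shape.tau_d
    for e in train.onsets_s:
        lo = np.searchsorted(t, e - 6.0 * spec.shape.tau_g - 1.0)
        hi = np.searchsorted(t, e + support)
        p = TransientModelParams(
            spec.shape.alpha_p, spec.shape.tau_g, spec.shape.tau_d, t0=e
        )
        y[lo:hi] += eval_kernel(p, t[lo:hi])
    if spec.drift_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        y += spec.drift_amp * np.sin(2 * np.pi * t / spec.drift_period_s + phase)
    if spec.noise_sd > 0:
        y += rng.normal(0.0, spec.noise_sd, size=len(t))
    return RawTrace(
        neuron_id=spec.neuron_id,
        session_id=design.session_id,
        sample_rate_hz=design.sample_rate_hz,
        samples=y,
        design=design,
    )


def true_onsets(train: TransientTrain, shape: TransientModelParams) -> np.ndarray:
    """Half-rise times of the rendered kernels (the ground-truth onsets the
    detector should recover)."""
    return train.onsets_s + kernel_onset(shape)


# ---------------------------------------------------------------------------
# velocity


def gen_velocity(
    design: SessionDesign,
    train: TransientTrain | None,
    coupling: str = "none",
    gain: float = 0.0,
    seed: int | np.random.Generator = 0,
    mean_speed: float = 3.0,
    relax_s: float = 2.0,
    sigma: float = 2.0,
) -> VelocityTrace:
    """Mean-reverting (Ornstein-Uhlenbeck-like) positive speed on the imaging
    frame grid, optionally coupled to transient times.

    With ``coupling='heightened'`` a gain-scaled Gaussian bump (SD 0.4 s,
    support about +/-1 s) is added at each event time; ``'lowered'``
    subtracts it.  Speeds are clipped at zero.
    """
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    t = design.frame_times()
    dt = 1.0 / design.sample_rate_hz
    theta = 1.0 / relax_s
    n = len(t)
    eps = rng.normal(0.0, 1.0, size=n - 1)
    a = np.exp(-theta * dt)
    s = sigma * np.sqrt((1 - a * a) / (2 * theta))
    # exact OU discretisation: AR(1) recursion run as an IIR filter
    dev = lfilter([s], [1.0, -a], eps)
    x = mean_speed + np.concatenate([[0.0], dev])
    if coupling != "none" and gain != 0.0 and train is not None and len(train) > 0:
        bump_sd = 0.4
        sign = 1.0 if coupling == "heightened" else -1.0
        for e in train.onsets_s:
            lo = np.searchsorted(t, e - 1.0)
            hi = np.searchsorted(t, e + 1.0)
            x[lo:hi] += sign * gain * np.exp(
                -0.5 * ((t[lo:hi] - e) / bump_sd) ** 2
            )
    return VelocityTrace(times_s=t, speed=np.clip(x, 0.0, None))


def velocity_to_centroid(
    vel: VelocityTrace,
    seed: int | np.random.Generator = 0,
    turn_sd: float = 0.5,
) -> pd.DataFrame:
    """Integrate a speed profile into an (x, y) centroid track with a
    random-walk heading, as a tracking system would report it."""
    rng = np.random.default_rng(seed)
    dt = np.diff(vel.times_s, prepend=vel.times_s[0] - np.median(np.diff(vel.times_s)))
    heading = np.cumsum(rng.normal(0.0, turn_sd * np.sqrt(np.abs(dt))))
    dx = vel.speed * dt * np.cos(heading)
    dy = vel.speed * dt * np.sin(heading)
    return pd.DataFrame(
        {"time_s": vel.times_s, "x": np.cumsum(dx), "y": np.cumsum(dy)}
    )


# ---------------------------------------------------------------------------
# photometry


def gen_photometry(
    duration_s: float = 1500.0,
    start_s: float = -600.0,
    artifact: tuple[float, float] = (1.8, 0.5),
    da_amplitude: float = 0.02,
    da_onset_s: float = 0.0,
    da_rise_s: float = 5.0,
    noise_sd: float = 0.002,
    sample_rate_hz: float = 20.0,
    seed: int | np.random.Generator = 0,
) -> tuple[PhotometrySignal, dict]:
    """Two-channel photometry with a shared motion/bleaching artifact.

    The control channel (405 nm) carries slow bleaching plus low-frequency
    motion; the signal channel (470 nm) is ``slope*ch405 + intercept`` plus a
    sigmoidal dopamine response whose plateau is ``da_amplitude`` relative to
    the artifact-predicted baseline, plus white noise.  Returns the signal and
    a ground-truth dict with the true relative dF/F.
    """
    rng = np.random.default_rng(seed)
    slope, intercept = artifact
    t = start_s + np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    bleach = 1.0 * np.exp(-(t - t[0]) / 5000.0)
    motion = 0.03 * np.sin(2 * np.pi * t / 97.0) + 0.02 * np.sin(
        2 * np.pi * t / 311.0 + 1.0
    )
    ch405_clean = bleach + motion
    ch470_clean = slope * ch405_clean + intercept
    # dopamine response: step at injection with a short saturating rise,
    # zero before onset so the pre-injection window stays artifact-only
    ramp = np.where(
        t >= da_onset_s, 1.0 - np.exp(-np.maximum(t - da_onset_s, 0.0) / da_rise_s), 0.0
    )
    da = da_amplitude * ch470_clean * ramp
    ch405 = ch405_clean + rng.normal(0.0, noise_sd, size=len(t))
    ch470 = ch470_clean + da + rng.normal(0.0, noise_sd, size=len(t))
    signal = PhotometrySignal(
        times_s=t, ch470=ch470, ch405=ch405, sample_rate_hz=sample_rate_hz
    )
    truth = {
        "da_amplitude": da_amplitude,
        "da_onset_s": da_onset_s,
        "true_dff": da / ch470_clean,
        "slope": slope,
        "intercept": intercept,
    }
    return signal, truth


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SynthConfig:
    """Configuration of a multi-animal, multi-session synthetic cohort."""

    out_dir: str = "scratch/cohort"
    seed: int = 0
    n_animals_per_class: int = 2
    n_neurons: int = 24
    days: tuple[str, ...] = ("saline", "cocaine1", "cocaine8")
    #: per-day fraction of responders in the class-preferred direction
    #: (elevated for D1-like animals, reduced for D2-like animals)
    responder_fractions: tuple[float, ...] = (0.05, 0.25, 0.45)
    base_rate_hz: tuple[float, float] = (0.08, 0.2)
    effect_multiplier: float = 3.0
    tracked_fraction: float = 0.7
    noise_sd: float = 0.15
    drift_amp: float = 0.3
    movement_fraction: float = 0.2
    movement_gain: float = 6.0
    #: per-day locomotion scale (saline low; day-8 cocaine ~1.4x day 1,
    #: emulating locomotor sensitization)
    day_locomotion_scale: tuple[float, ...] = (0.3, 1.0, 1.4)
    photometry: bool = True
    da_amplitudes: tuple[float, ...] = (0.0, 0.02, 0.02)

    def __post_init__(self) -> None:
        if len(self.responder_fractions) != len(self.days):
            raise DesignError("one responder fraction per day required")


def _neuron_specs_for_animal(
    cfg: SynthConfig, animal: str, class_tag: str, rng: np.random.Generator
) -> dict[str, dict]:
    """Per-neuron static properties shared across days."""
    lo, hi = cfg.base_rate_hz
    out = {}
    n_mov = int(round(cfg.movement_fraction * cfg.n_neurons))
    mov_idx = set(rng.choice(cfg.n_neurons, size=n_mov, replace=False).tolist())
    for i in range(cfg.n_neurons):
        out[f"{animal}_n{i:03d}"] = {
            "index": i,
            "base_rate": float(rng.uniform(lo, hi)),
            "movement": i in mov_idx,
        }
    return out


def gen_cohort(config: SynthConfig) -> tuple[Path, SynthGroundTruth]:
    """Write a full cohort to ``config.out_dir`` and return its ground truth.

    Layout: one traces CSV (neuron_id, time_s, fluorescence) and one centroid
    CSV (time_s, x, y) per animal per day, optional photometry CSV
    (time_s, ch470, ch405), a design JSON per day, a cross-session identity
    map JSON per animal, and a ground-truth JSON for the whole cohort.

    Responder sets are nested across days (a neuron responsive on an earlier
    cocaine day stays responsive later), so tracked neurons fall into both
    the "both sessions" and "last exposure only" cross-session categories.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    truth = SynthGroundTruth(seed=config.seed)
    identity: dict[str, dict] = {}

    animals = [
        (f"{tag.split('-')[0].lower()}_m{i}", tag)
        for tag in ("D1-like", "D2-like")
        for i in range(config.n_animals_per_class)
    ]
    for (animal, class_tag), a_ss in zip(animals, root.spawn(len(animals))):
        rng = np.random.default_rng(a_ss)
        static = _neuron_specs_for_animal(config, animal, class_tag, rng)
        n_tracked = int(round(config.tracked_fraction * config.n_neurons))
        tracked = list(static)[:n_tracked]
        identity[animal] = {
            "tracked_ids": {
                f"{animal}_t{j:03d}": {day: nid for day in config.days}
                for j, nid in enumerate(tracked)
            }
        }
        for d_i, day in enumerate(config.days):
            design = SessionDesign(session_id=day)
            frac = config.responder_fractions[d_i]
            k = int(round(frac * config.n_neurons))
            rows_t, rows_time, rows_f = [], [], []
            all_events: list[np.ndarray] = []
            for nid, st in static.items():
                responder = st["index"] < k  # nested responder sets across days
                base = st["base_rate"]
                if responder and class_tag == "D1-like":
                    pre, post, label = base, base * config.effect_multiplier, "elevated"
                elif responder:
                    pre, post, label = base, base / config.effect_multiplier, "reduced"
                else:
                    pre = post = base
                    label = "none"
                spec = SynthNeuronSpec(
                    neuron_id=nid,
                    class_tag=class_tag,
                    rate_pre_hz=pre,
                    rate_post_hz=post,
                    true_label=label,
                    noise_sd=config.noise_sd,
                    drift_amp=config.drift_amp,
                    velocity_coupling="heightened" if st["movement"] else "none",
                    coupling_gain=config.movement_gain if st["movement"] else 0.0,
                )
                train = gen_event_train(spec, design, rng)
                trace = render_trace(train, spec, design, rng)
                key = f"{animal}/{day}/{nid}"
                truth.specs[key] = spec
                truth.event_t0s[key] = train.onsets_s
                truth.event_onsets[key] = true_onsets(train, spec.shape)
                all_events.append(train.onsets_s)
                t = design.frame_times()
                rows_t.append(np.repeat(nid, len(t)))
                rows_time.append(t)
                rows_f.append(trace.samples)
            df = pd.DataFrame(
                {
                    "neuron_id": np.concatenate(rows_t),
                    "time_s": np.concatenate(rows_time),
                    "fluorescence": np.concatenate(rows_f),
                }
            )
            df.to_csv(out / f"{animal}_{day}_traces.csv", index=False, float_format="%.5f")
            # one behavioural track per animal/day, coupled to the pooled
            # events of the movement-coupled neurons
            mov_events = np.sort(
                np.concatenate(
                    [
                        ev
                        for ev, st in zip(all_events, static.values())
                        if st["movement"]
                    ]
                    or [np.array([])]
                )
            )
            pooled = (
                TransientTrain(animal, day, np.unique(mov_events))
                if len(mov_events)
                else None
            )
            scale = config.day_locomotion_scale[d_i]
            vel = gen_velocity(
                design,
                pooled,
                coupling="heightened" if pooled is not None else "none",
                gain=config.movement_gain * scale if pooled is not None else 0.0,
                seed=rng,
                mean_speed=3.0 * scale,
                sigma=2.0 * scale,
            )
            velocity_to_centroid(vel, seed=rng).to_csv(
                out / f"{animal}_{day}_centroid.csv", index=False, float_format="%.4f"
            )
            if config.photometry:
                sig, ph_truth = gen_photometry(
                    da_amplitude=config.da_amplitudes[d_i], seed=rng
                )
                pd.DataFrame(
                    {"time_s": sig.times_s, "ch470": sig.ch470, "ch405": sig.ch405}
                ).to_csv(
                    out / f"{animal}_{day}_photometry.csv",
                    index=False,
                    float_format="%.6f",
                )
            (out / f"design_{day}.json").write_text(
                json.dumps(design.to_dict(), indent=1)
            )
    (out / "identity_map.json").write_text(json.dumps(identity, indent=1))
    truth.to_json(out / "ground_truth.json")
    import yaml

    (out / "config.yaml").write_text(
        yaml.safe_dump(json.loads(json.dumps(asdict(config))))
    )
    return out, truth
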