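"""Synthetic MEG epoch generation with category-specific evoked responses.

A simulated subject views 14 white-on-black images — 4 feet, 4 hands, 4
mouths, 2 objects — 40 times each in pseudo-random order (560 trials).
Each body-part trial evokes a transient dipolar source in an
occipitotemporal patch: a *shared* vertex set common to all body parts
(the body-sensitive response) plus a *category-unique* vertex set that
carries the category information. Object trials activate an early-visual
patch instead. Source currents are projected to the helmet through the
spherical-conductor lead field, and background brain noise (random
dipoles with 1/f spectra) plus white sensor noise are added.

All randomness flows from a single seed through ``numpy.random.Generator``
/ ``SeedSequence``, so a fixed seed reproduces a cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import LeadField, compute_lead_field
from .geometry import SensorArray, SourceSpace, build_geometry

CATEGORIES = ("foot", "hand", "mouth", "object")
BODY_CATEGORIES = ("foot", "hand", "mouth")


class TemplateError(ValueError):
    """Raised when an evoked template is inconsistent with the source space."""


@dataclass(frozen=True)
class StimulusSet:
    """The 14-image stimulus set: image id -> category, with repetition count."""

    image_ids: np.ndarray  # (14,) int
    category: np.ndarray  # (14,) str
    repetitions: int = 40

    @classmethod
    def default(cls, repetitions: int = 40) -> "StimulusSet":
        cats = ["foot"] * 4 + ["hand"] * 4 + ["mouth"] * 4 + ["object"] * 2
        return cls(
            image_ids=np.arange(1, 15),
            category=np.asarray(cats, dtype=object),
            repetitions=repetitions,
        )

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    @property
    def n_trials(self) -> int:
        return self.n_images * self.repetitions

    def body_image_ids(self) -> np.ndarray:
        return self.image_ids[np.isin(self.category, BODY_CATEGORIES)]

    def schedule(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Pseudo-random presentation order: (image_id, category) per trial."""
        ids = np.repeat(self.image_ids, self.repetitions)
        order = rng.permutation(len(ids))
        ids = ids[order]
        cat_of = dict(zip(self.image_ids.tolist(), self.category.tolist()))
        cats = np.asarray([cat_of[i] for i in ids], dtype=object)
        return ids, cats


@dataclass(frozen=True)
class EvokedTemplate:
    """Spatiotemporal template of the body-sensitive evoked response.

    ``shared_vertices`` respond identically for every body-part category;
    ``unique_vertices[cat]`` respond only to that category, scaled by
    ``category_effect`` (0 removes all category information) and by the
    per-category ``amp_scale``. ``object_vertices`` respond to object
    trials only. The temporal kernel is a smooth unimodal pulse, zero
    outside [onset, offset] ms, peaking at ``peak_ms``.
    """

    shared_vertices: np.ndarray
    unique_vertices: dict[str, np.ndarray]
    object_vertices: np.ndarray
    amplitude_nam: float = 0.8  # per-vertex source strength, nA·m
    category_effect: float = 1.0
    amp_scale: dict[str, float] = field(
        default_factory=lambda: {"foot": 1.0, "hand": 1.0, "mouth": 1.3}
    )
    onset_ms: float = 120.0
    peak_ms: float = 190.0
    offset_ms: float = 300.0
    image_gain_sd: float = 0.10

    def kernel(self, times_ms: np.ndarray) -> np.ndarray:
        """Unimodal pulse: sin^2 rise to the peak, cos^2 fall after it."""
        t = np.asarray(times_ms, dtype=float)
        k = np.zeros_like(t)
        rise = (t >= self.onset_ms) & (t <= self.peak_ms)
        fall = (t > self.peak_ms) & (t <= self.offset_ms)
        k[rise] = np.sin(
            0.5 * np.pi * (t[rise] - self.onset_ms) / (self.peak_ms - self.onset_ms)
        ) ** 2
        k[fall] = np.cos(
            0.5 * np.pi * (t[fall] - self.peak_ms) / (self.offset_ms - self.peak_ms)
        ) ** 2
        return k

    def active_vertices(self, category: str) -> np.ndarray:
        if category == "object":
            return self.object_vertices
        return np.concatenate([self.shared_vertices, self.unique_vertices[category]])

    def validate(self, n_vertices: int) -> None:
        allv = np.concatenate(
            [self.shared_vertices, self.object_vertices]
            + [v for v in self.unique_vertices.values()]
        )
        if allv.size and (allv.min() < 0 or allv.max() >= n_vertices):
            raise TemplateError("template references vertices outside the source space")


def make_template(
    sources: SourceSpace,
    n_shared: int = 12,
    n_unique: int = 6,
    seed: int = 0,
    **kwargs,
) -> EvokedTemplate:
    """Draw template vertex sets from the tagged source regions.

    Shared vertices come from the occipitotemporal body patch (eba+fba),
    one disjoint unique set per body category from the same patch, and the
    object set from the early-visual patch. With the default half/half
    split the response is ~50% shared, ~50% category-unique per trial.
    """
    rng = np.random.default_rng(seed)
    body_pool = np.concatenate([sources.vertices_in("eba"), sources.vertices_in("fba")])
    need = n_shared + 3 * n_unique
    if len(body_pool) < need:
        # sparse source grids: grow the patch outward from the
        # posterior-inferior direction until it can hold the template
        c = np.array([0.0, -0.7, -0.5])
        c /= np.linalg.norm(c)
        units = sources.positions / np.linalg.norm(
            sources.positions, axis=1, keepdims=True
        )
        order = np.argsort(-(units @ c))
        extra = [v for v in order if v not in set(body_pool.tolist())]
        body_pool = np.concatenate([body_pool, np.asarray(extra, dtype=int)])[
            : max(need, len(body_pool))
        ]
    if len(body_pool) < need:
        raise TemplateError(
            f"body patch has {len(body_pool)} vertices, template needs {need}"
        )
    picked = rng.choice(body_pool, size=need, replace=False)
    shared = picked[:n_shared]
    unique = {
        cat: picked[n_shared + i * n_unique : n_shared + (i + 1) * n_unique]
        for i, cat in enumerate(BODY_CATEGORIES)
    }
    ev_pool = sources.vertices_in("early_visual")
    ev_pool = np.setdiff1d(ev_pool, picked)
    if len(ev_pool) == 0:
        ev_pool = np.setdiff1d(sources.vertices_in("background"), picked)
    if len(ev_pool) == 0:
        ev_pool = np.setdiff1d(np.arange(sources.n_vertices), picked)
    n_obj = min(n_shared, len(ev_pool))
    obj = rng.choice(ev_pool, size=n_obj, replace=False)
    return EvokedTemplate(
        shared_vertices=np.sort(shared),
        unique_vertices={c: np.sort(v) for c, v in unique.items()},
        object_vertices=np.sort(obj),
        **kwargs,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Sensor white noise, 1/f background dipoles, and per-subject gain jitter."""

    sensor_noise_sd: float = 100e-15  # tesla, per raw sample
    n_background: int = 30  # random background dipoles per trial
    background_amp_sd: float = 3.0  # nA·m
    gain_jitter_sd: float = 0.05  # multiplicative per-channel, per subject

    def __post_init__(self) -> None:
        if min(self.sensor_noise_sd, self.background_amp_sd, self.gain_jitter_sd) < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class EpochSet:
    """Trials x channels x samples of MEG field values with per-trial labels."""

    data: np.ndarray  # (trials, channels, samples), tesla
    times: np.ndarray  # (samples,) ms
    image_id: np.ndarray  # (trials,) int
    category: np.ndarray  # (trials,) str
    sensors: SensorArray
    sfreq: float = 1000.0
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length mismatch")
        if self.data.shape[1] != self.sensors.n_channels:
            raise ValueError("channel axis does not match sensor array")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **changes) -> "EpochSet":
        return replace(self, **changes)

    def time_mask(self, tmin_ms: float, tmax_ms: float) -> np.ndarray:
        return (self.times >= tmin_ms) & (self.times < tmax_ms)

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        return replace(
            self,
            data=self.data[mask],
            image_id=self.image_id[mask],
            category=self.category[mask],
        )


def _one_over_f(rng: np.random.Generator, n_series: int, n_samples: int, sfreq: float) -> np.ndarray:
    """Gaussian series with ~1/f power spectra, unit variance per series."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 => power ~ 1/f
    spec = (
        rng.standard_normal((n_series, len(freqs)))
        + 1j * rng.standard_normal((n_series, len(freqs)))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic cohort."""

    n_channels: int = 160
    n_vertices: int = 4004
    head_radius: float = 0.09
    sfreq: float = 1000.0
    tmin_ms: float = -500.0
    tmax_ms: float = 500.0
    repetitions: int = 40
    n_shared: int = 12
    n_unique: int = 6
    amplitude_nam: float = 0.8
    category_effect: float = 1.0
    image_gain_sd: float = 0.10
    peak_ms: float = 190.0
    sensor_noise_sd: float = 100e-15
    n_background: int = 30
    background_amp_sd: float = 3.0
    gain_jitter_sd: float = 0.05

    def stimuli(self) -> StimulusSet:
        return StimulusSet.default(repetitions=self.repetitions)

    def noise(self) -> NoiseModel:
        return NoiseModel(
            sensor_noise_sd=self.sensor_noise_sd,
            n_background=self.n_background,
            background_amp_sd=self.background_amp_sd,
            gain_jitter_sd=self.gain_jitter_sd,
        )


def simulate_subject(
    stimuli: StimulusSet,
    template: EvokedTemplate,
    noise: NoiseModel,
    leadfield: LeadField,
    sensors: SensorArray,
    seed: int,
    sfreq: float = 1000.0,
    tmin_ms: float = -500.0,
    tmax_ms: float = 500.0,
    subject_id: str = "S00",
) -> EpochSet:
    """Simulate one subject's epoch set.

    Each trial's sensor data is ``jittered_gain @ source_currents`` for the
    trial's category (scaled by a fixed per-image gain factor), plus
    projected 1/f background dipoles, plus white sensor noise. Deterministic
    given ``seed``.
    """
    template.validate(leadfield.n_vertices)
    rng = np.random.default_rng(seed)
    n_samples = int(round((tmax_ms - tmin_ms) * sfreq / 1000.0))
    times = tmin_ms + np.arange(n_samples) * 1000.0 / sfreq

    # per-subject multiplicative channel gain jitter
    jitter = 1.0 + noise.gain_jitter_sd * rng.standard_normal(leadfield.n_channels)
    gain = leadfield.gain * jitter[:, None]

    kernel = template.kernel(times)  # (samples,)

    # fixed per-image amplitude perturbation (image identity, not category)
    image_gain = 1.0 + template.image_gain_sd * rng.standard_normal(stimuli.n_images)
    image_gain_of = dict(zip(stimuli.image_ids.tolist(), image_gain.tolist()))

    # per-category sensor-space spatial pattern (tesla at kernel peak)
    pattern: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        amp = np.zeros(leadfield.n_vertices)
        if cat == "object":
            amp[template.object_vertices] = template.amplitude_nam
        else:
            amp[template.shared_vertices] = template.amplitude_nam
            amp[template.unique_vertices[cat]] = (
                template.amplitude_nam
                * template.category_effect
                * template.amp_scale.get(cat, 1.0)
            )
        pattern[cat] = gain @ (amp * 1e-9)  # nA·m -> A·m

    ids, cats = stimuli.schedule(rng)
    n_trials = len(ids)
    n_ch = leadfield.n_channels
    data = np.empty((n_trials, n_ch, n_samples))

    for t in range(n_trials):
        sig = image_gain_of[int(ids[t])] * np.outer(pattern[cats[t]], kernel)
        if noise.n_background > 0 and noise.background_amp_sd > 0:
            bg_idx = rng.integers(0, leadfield.n_vertices, size=noise.n_background)
            bg_amp = noise.background_amp_sd * 1e-9 * rng.standard_normal(
                noise.n_background
            )
            bg_ts = _one_over_f(rng, noise.n_background, n_samples, sfreq)
            sig = sig + (gain[:, bg_idx] * bg_amp) @ bg_ts
        data[t] = sig
    if noise.sensor_noise_sd > 0:
        data += noise.sensor_noise_sd * rng.standard_normal(data.shape)

    return EpochSet(
        data=data,
        times=times,
        image_id=ids.astype(int),
        category=cats,
        sensors=sensors,
        sfreq=sfreq,
        subject_id=subject_id,
    )


@dataclass(frozen=True)
class HeadModel:
    """Canonical geometry + lead field + evoked template shared by a cohort.

    All subjects are expressed in one "normalized" source space (as after
    anatomical normalization), so per-vertex statistics can be averaged
    across subjects. Between-subject variability enters through the
    per-channel gain jitter and the per-subject noise draws instead.
    """

    sensors: SensorArray
    sources: SourceSpace
    leadfield: LeadField
    template: EvokedTemplate


def build_model(config: SimulationConfig, seed: int = 0) -> HeadModel:
    """Build the cohort-level geometry, lead field and evoked template."""
    sensors, sources = build_geometry(
        n_channels=config.n_channels,
        n_vertices=config.n_vertices,
        head_radius=config.head_radius,
        seed=seed,
    )
    leadfield = compute_lead_field(sensors, sources)
    template = make_template(
        sources,
        n_shared=config.n_shared,
        n_unique=config.n_unique,
        seed=seed,
        amplitude_nam=config.amplitude_nam,
        category_effect=config.category_effect,
        image_gain_sd=config.image_gain_sd,
        peak_ms=config.peak_ms,
    )
    return HeadModel(sensors, sources, leadfield, template)


def generate_subject(
    config: SimulationConfig,
    seed: int,
    model: HeadModel | None = None,
    subject_id: str = "S00",
) -> EpochSet:
    """Simulate one subject's epochs (building a head model if not given)."""
    if model is None:
        model = build_model(config, seed)
    return simulate_subject(
        config.stimuli(),
        model.template,
        config.noise(),
        model.leadfield,
        model.sensors,
        seed=seed,
        sfreq=config.sfreq,
        tmin_ms=config.tmin_ms,
        tmax_ms=config.tmax_ms,
        subject_id=subject_id,
    )


def cohort_model_seed(seed: int) -> int:
    """Seed of the shared head model derived from a cohort master seed."""
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))


def generate_cohort(
    n_subjects: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    model: HeadModel | None = None,
) -> tuple[HeadModel, list[EpochSet]]:
    """Simulate ``n_subjects`` independent subjects from one master seed.

    Returns the shared head model and the list of epoch sets.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if config is None:
        config = SimulationConfig()
    ss = np.random.SeedSequence(seed)
    subject_seeds = (ss.generate_state(n_subjects + 1) % (2**31))[1:]
    if model is None:
        model = build_model(config, cohort_model_seed(seed))
    epochs = [
        generate_subject(config, int(s), model=model, subject_id=f"S{i + 1:02d}")
        for i, s in enumerate(subject_seeds)
    ]
    return model, epochs
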