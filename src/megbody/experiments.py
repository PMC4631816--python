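"""Predefined simulation experiments: null calibration, scheme separation,
source parameter recovery.

These protocols wrap the full pipeline into the three Monte-Carlo
experiments the package uses to validate itself:

* ``chance_recovery`` — decoding with the category effect (and per-image
  gain variation) switched off must average to the 3-class chance rate.
* ``scheme_separation`` — with the default category effect, categorical
  decoding must beat the image-identity-preserving random-class null,
  both at the peak and by a paired t-test across subjects.
* ``parameter_recovery`` — vertices with high category-contrast F values
  must overlap the simulated category-unique sources.

All run at reduced problem sizes (fewer channels and vertices, shorter
sampling, 10 repetitions per image) so a full experiment takes minutes on
one core; the trial structure (14 images, 3 body categories + objects,
balanced repetitions, 10-fold CV) matches the study design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import decode as dec
from . import source as src
from .preprocess import PreprocessConfig, preprocess
from .simulate import SimulationConfig, build_model, generate_cohort, generate_subject

#: null condition: tiny subjects with no category information at all
NULL_CONFIG = SimulationConfig(
    n_channels=8,
    n_vertices=16,
    repetitions=10,
    sfreq=250.0,
    n_shared=4,
    n_unique=2,
    category_effect=0.0,
    image_gain_sd=0.0,
    amplitude_nam=2.0,
    n_background=5,
)

#: effect condition: scaled-down cohort with the default category effect
EFFECT_CONFIG = SimulationConfig(
    n_channels=32,
    n_vertices=200,
    repetitions=10,
    sfreq=250.0,
    amplitude_nam=2.0,
    n_background=10,
)

#: keep all channels in the tiny null geometry (too few to spare any)
NULL_PREPROCESS = PreprocessConfig(excluded_region="none-excluded")


def _seeds(master_seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n) % (2**31)]


def chance_recovery(
    n_seeds: int = 50,
    seed: int = 0,
    config: SimulationConfig = NULL_CONFIG,
) -> dict:
    """Mean categorical decoding accuracy under the information-free null.

    Simulates ``n_seeds`` independent null subjects (zero category effect,
    no per-image gain variation), runs the full sliding-window pipeline
    with the categorical labelling, and averages accuracy over all windows
    and seeds. Returns the mean accuracy, its Monte-Carlo standard error
    over seeds, and the per-seed means.
    """
    per_seed = []
    for s in _seeds(seed, n_seeds):
        epochs = generate_subject(config, seed=s)
        clean, _ = preprocess(epochs, NULL_PREPROCESS)
        feats = dec.extract_features(clean)
        res = dec.crossval_decode(feats, dec.make_labels(config.stimuli()), seed=s)
        per_seed.append(float(res.accuracy.mean()))
    per_seed = np.asarray(per_seed)
    return {
        "mean_accuracy": float(per_seed.mean()),
        "mc_se": float(per_seed.std(ddof=1) / np.sqrt(len(per_seed))),
        "per_seed": per_seed,
        "n_windows": res.accuracy.size,
        "n_trials": res.n_trials,
    }


@dataclass
class CohortSeparation:
    peak_categorical: float
    peak_random: float
    paired_p_at_peak: float
    paired_p_at_190ms: float
    peak_window_ms: float


def scheme_separation_cohort(
    cohort_seed: int,
    n_subjects: int = 9,
    config: SimulationConfig = EFFECT_CONFIG,
    n_partitions: int = 3,
    decode_range: tuple[float, float] = (0.0, 300.0),
) -> CohortSeparation:
    """Categorical vs random-class decoding for one simulated cohort.

    Decoding runs over 20-ms windows slid by 10 ms across
    ``decode_range``; the paired t-test compares per-subject accuracies at
    the group-level categorical peak and at the 190-ms window (the
    simulated response peak).
    """
    model, cohort = generate_cohort(n_subjects, config, seed=cohort_seed)
    cat_results, rnd_results = [], []
    stimuli = config.stimuli()
    for i, raw in enumerate(cohort):
        clean, _ = preprocess(raw, PreprocessConfig())
        feats = dec.extract_features(clean, trange=decode_range)
        cat_results.append(
            dec.decode_subject(
                clean, "categorical", stimuli, seed=cohort_seed + i,
                featureset=feats,
            )
        )
        rnd_results.append(
            dec.decode_subject(
                clean, "random", stimuli, n_partitions=n_partitions,
                seed=cohort_seed + i, featureset=feats,
            )
        )
    result = dec.test_significance(cat_results, rnd_results)
    pk = int(np.argmax(result.categorical_mean))
    i190 = int(np.argmin(np.abs(result.window_centers - 190.0)))
    return CohortSeparation(
        peak_categorical=float(result.categorical_mean.max()),
        peak_random=float(result.random_mean.max()),
        paired_p_at_peak=float(result.paired_p[pk]),
        paired_p_at_190ms=float(result.paired_p[i190]),
        peak_window_ms=float(result.window_centers[pk]),
    )


def scheme_separation(
    n_cohorts: int = 20, seed: int = 0, n_subjects: int = 9, **kwargs
) -> list[CohortSeparation]:
    return [
        scheme_separation_cohort(s, n_subjects=n_subjects, **kwargs)
        for s in _seeds(seed, n_cohorts)
    ]


def parameter_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    config: SimulationConfig = EFFECT_CONFIG,
    lam: float = 0.1,
) -> dict:
    """Source-level recovery of the category-unique vertex set.

    Per seed: simulate one subject, preprocess, build the minimum-norm
    inverse from the baseline covariance, F-map the 3-category contrast at
    180–200 ms, and measure the Jaccard overlap between the top-decile F
    vertices and the simulated category-unique set.
    """
    model = build_model(config, seed=seed)
    uniq = np.sort(np.concatenate(list(model.template.unique_vertices.values())))
    n_top = max(1, config.n_vertices // 10)

    def top_decile_jaccard(f_values: np.ndarray) -> float:
        top = np.argsort(f_values)[-n_top:]
        inter = len(np.intersect1d(top, uniq))
        return inter / len(np.union1d(top, uniq))

    jaccards, maps = [], []
    for s in _seeds(seed + 1, n_seeds):
        epochs = generate_subject(config, seed=s, model=model)
        clean, _ = preprocess(epochs, PreprocessConfig())
        ch_mask = np.isin(model.sensors.channel_ids, clean.sensors.channel_ids)
        lf = model.leadfield.subset_channels(ch_mask)
        cov = src.estimate_noise_covariance(clean)
        inv = src.compute_inverse_filter(lf, cov, lam=lam, epochs=clean)
        est = src.apply_inverse(inv, clean)
        fm = src.f_map(est)
        maps.append(fm)
        jaccards.append(top_decile_jaccard(fm.f_values))
    averaged = src.average_f_maps(maps)
    return {
        "jaccard": np.asarray(jaccards),
        "mean_jaccard": float(np.mean(jaccards)),
        "jaccard_of_averaged_map": top_decile_jaccard(averaged.f_values),
        "n_top": n_top,
        "n_unique": len(uniq),
    }
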