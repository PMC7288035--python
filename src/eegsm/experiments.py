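"""Study-scale experiment recipes.

These functions run the package's two headline analyses end to end at the
study's stated scale (14 subject pairs, 4 x 60 s recordings at 128 Hz) and
return their metrics.  They exist so that validation scripts and tests
exercise exactly the same code path a user would.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .correlation import (HypothesisReport, average_correlation,
                          correlation_matrix, evaluate_hypotheses)
from .montage import CATEGORIES
from .preprocessing import preprocess
from .soft_sensor import (ClassifierSpec, SoftSensor, accuracy, evaluate,
                          plan_split, shuffle_labels, stack_images)
from .synthetic import (build_target_correlation, default_profiles,
                        generate_study, identity_profiles, separable_profiles)
from .topomap import render_recording


def correlation_recovery(seed: int, n_pairs: int = 14, duration_s: float = 60.0,
                         rate_hz: float = 128.0, profiles=None) -> dict:
    """Generate -> preprocess -> correlate -> hypothesis verdicts.

    Returns the per-category Fisher-averaged matrices, the largest
    elementwise deviation from the generator targets, and the hypothesis
    report at default thresholds.
    """
    profiles = profiles or default_profiles()
    targets = {c: build_target_correlation(p) for c, p in profiles.items()}
    ds = generate_study(n_pairs, profiles, seed,
                        duration_s=duration_s, rate_hz=rate_hz)
    pre = ds.map(preprocess)
    cat_mats = {}
    max_err = 0.0
    for cat in CATEGORIES:
        mats = [correlation_matrix(r) for r in pre.by_category(cat)]
        avg = average_correlation(mats, "fisher_z")
        cat_mats[cat] = avg
        max_err = max(max_err, float(np.max(np.abs(avg.values - targets[cat].values))))
    report = evaluate_hypotheses(cat_mats)
    return {"category_matrices": cat_mats, "max_abs_error": max_err,
            "report": report}


def identity_control(seed: int, n_pairs: int = 14) -> HypothesisReport:
    """Same analysis on uncorrelated data: no strong coupling should show."""
    return correlation_recovery(seed, n_pairs,
                                profiles=identity_profiles())["report"]


def classifier_study(seed: int, n_pairs: int = 14,
                     spec: ClassifierSpec | None = None,
                     shuffled_epochs: int = 3) -> dict:
    """Pair-held-out soft-sensor validation on the separable profile set.

    Trains at desk scale (90 px images, reduced filter counts — see
    ClassifierSpec.desk_scale) on a 10/2/2 pair split, then repeats the
    training with permuted labels as a negative control; the control model
    is evaluated against the *true* test labels and should sit at chance.
    """
    spec = spec or ClassifierSpec.desk_scale()
    ds = generate_study(n_pairs, separable_profiles(), seed)
    pre = ds.map(preprocess)
    maps = []
    for rec in pre:
        maps += render_recording(rec, grid_n=spec.input_size)
    images = stack_images(maps)
    n_test = max(1, round(n_pairs * 2 / 14))
    n_val = max(1, round(n_pairs * 2 / 14))
    plan = plan_split(sorted(set(images.pair_ids.tolist())),
                      n_pairs - n_val - n_test, n_val, n_test, seed)
    results = SoftSensor(spec).fit(images, plan, seed=seed)
    test = images.for_split(plan, "test")
    cm = results.evaluate(test)

    control_spec = dataclasses.replace(spec, epochs=shuffled_epochs)
    shuffled = shuffle_labels(images, seed=seed + 1)
    control = SoftSensor(control_spec).fit(shuffled, plan, seed=seed)
    cm_control = evaluate(control.model, test)

    return {
        "results": results,
        "confusion": cm,
        "test_accuracy": accuracy(cm),
        "shuffled_accuracy": accuracy(cm_control),
        "n_train_images": len(images.for_split(plan, "train")),
        "n_val_images": len(images.for_split(plan, "validation")),
        "n_test_images": len(test),
    }
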