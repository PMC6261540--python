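"""The packaged end-to-end study on synthetic cohorts.

This module fixes the study conditions under which the whole pipeline —
cohort generation, voronoi rasterization, training, grouped
cross-validation, AP scoring — is exercised and reported:

* cohort: 20 control + 20 early-glaucoma subjects, one eye each, three
  visits per eye (120 examinations) on the 24-2 pattern, with the default
  calibration of the synthetic generator (moderate focal defects);
* protocol: 10-fold subject-grouped cross-validation; neural methods are
  trained twice per fold with distinct seeds, 25-epoch budget with
  best-validation-loss checkpointing.  This is a scaled-down protocol chosen
  so a full run finishes in minutes on one CPU; the training repeat count
  and epoch budget are the only deviations from the package defaults.

``run_null_study`` re-runs the same pipeline with every defect depth set to
zero, so the two groups are statistically identical: all methods should then
fall to the prevalence regime (AP scattering around the positive class
fraction, 0.5 in the balanced cohort).  The null check uses a lighter
protocol (5 folds, one repeat, 10 epochs) since only the regime matters.
"""

from __future__ import annotations

import dataclasses

from .evaluation import METHODS, CVReport, run_cv
from .models import ModelSpec
from .synthetic import SynthConfig, generate_dataset

SCALED_EPOCHS = 25
SCALED_REPEATS = 2
SCALED_FOLDS = 10


def scaled_config(seed: int) -> SynthConfig:
    """The default study cohort: 20 + 20 subjects, 3 visits, one eye."""
    return SynthConfig(seed=seed % (2**31))


def null_config(seed: int) -> SynthConfig:
    """Same cohort shape with all defect depths forced to zero."""
    return dataclasses.replace(
        scaled_config(seed),
        defect_depth_mean=0.0,
        defect_depth_sd=0.0,
        diffuse_depth_mean=0.0,
        diffuse_depth_sd=0.0,
        progression_per_visit=0.0,
    )


def run_scaled_study(seed: int = 7, methods=METHODS) -> CVReport:
    """Full cross-validated comparison of all methods on the default cohort."""
    config = scaled_config(seed)
    records, _ = generate_dataset(config)
    pattern = config.resolve_pattern()
    spec = ModelSpec(epochs=SCALED_EPOCHS)
    return run_cv(
        records, pattern, methods=methods, k=SCALED_FOLDS, repeats=SCALED_REPEATS,
        seed=seed % (2**31), model_spec=spec,
    )


def run_null_study(seed: int = 7, methods=METHODS) -> CVReport:
    """The zero-depth control experiment (prevalence-regime check)."""
    config = null_config(seed)
    records, _ = generate_dataset(config)
    pattern = config.resolve_pattern()
    spec = ModelSpec(epochs=10)
    return run_cv(
        records, pattern, methods=methods, k=5, repeats=1,
        seed=seed % (2**31), model_spec=spec,
    )
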