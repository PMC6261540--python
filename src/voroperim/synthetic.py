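"""Synthetic visual-field cohorts with early-glaucoma defect structure.

The generator emulates the statistical shape of longitudinal perimetry
cohorts: two groups of subjects (control and early glaucoma, EG), one or two
eyes per subject, several visits per eye, and per-examination deviation
vectors on a chosen test pattern.

Control fields are a per-eye global offset (small systematic deviation from
age-normal) plus independent per-location test-retest noise.  EG fields add,
on top of the same background, a persistent focal defect at one *archetype*
— a named set of pattern locations shaped like the classic early-glaucoma
scotomas (superior/inferior arcuate, nasal step, superior paracentral) — or
a mild diffuse depression.  Defects deepen slowly across visits.  Both
groups are rejection-sampled to MD < 6.0 dB, the usual early-stage
inclusion cap.

Default noise and offset levels are calibrated so the control group matches
reported clinical cohorts (mean MD about -0.31 dB, mean sLV about 1.84 dB);
focal depth defaults to 14 +/- 4 dB, which puts EG mean MD in the 2-3 dB
range under the cap.  Archetype membership is stored as plain location-index
lists in the config (data, not code), derived geometrically from the pattern
when not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .indices import mean_defect
from .io import TestPattern, VisualFieldRecord, bundled_pattern, write_vf_table

FOCAL_ARCHETYPES = ("superior_arcuate", "inferior_arcuate", "nasal_step", "paracentral")


def default_archetypes(pattern: TestPattern) -> dict[str, list[int]]:
    """Geometric archetype location sets for a pattern (OD orientation).

    * superior/inferior arcuate: the 10-20 degree annulus in one hemifield,
      sweeping from the temporal arc toward the nasal horizontal;
    * nasal step: the superior nasal wedge at and beyond 15 degrees;
    * paracentral: locations within 10 degrees in the superior hemifield;
    * diffuse: every non-blind-spot location.
    """
    x, y = pattern.x, pattern.y
    r = np.hypot(x, y)
    usable = pattern.usable
    sets = {
        "superior_arcuate": (r >= 10) & (r <= 20) & (y > 0) & usable,
        "inferior_arcuate": (r >= 10) & (r <= 20) & (y < 0) & usable,
        "nasal_step": (x <= -15) & (y > 0) & (y <= 10) & usable,
        "paracentral": (r <= 10) & (y > 0) & usable,
        "diffuse": usable,
    }
    out = {}
    for name, mask in sets.items():
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"archetype {name!r} is empty for pattern {pattern.pattern_id!r}")
        out[name] = [int(i) for i in idx]
    return out


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    All dB quantities follow the deviation convention (loss negative);
    ``defect_depth_mean`` is the positive magnitude of the focal loss.
    """

    pattern_id: str = "24-2"
    n_control_subjects: int = 20
    n_eg_subjects: int = 20
    visits_per_eye: tuple[int, int] = (3, 3)  # inclusive range
    eyes_per_subject: int = 1
    control_noise_sd: float = 1.84  # per-location test-retest noise, dB
    control_offset_mean: float = 0.31  # per-eye systematic deviation, dB
    control_offset_sd: float = 1.0
    defect_depth_mean: float = 14.0  # focal loss magnitude, dB
    defect_depth_sd: float = 4.0
    diffuse_depth_mean: float = 2.5  # mild generalized depression, dB
    diffuse_depth_sd: float = 0.8
    progression_per_visit: float = 0.3  # added focal depth per visit, dB
    md_cap: float = 6.0  # emitted records satisfy MD < md_cap
    archetypes: Optional[dict[str, list[int]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("control_noise_sd", "control_offset_sd", "defect_depth_sd",
                     "diffuse_depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eyes_per_subject not in (1, 2):
            raise ValueError("eyes_per_subject must be 1 or 2")
        lo, hi = self.visits_per_eye
        if not (1 <= lo <= hi):
            raise ValueError("visits_per_eye must be a non-empty inclusive range")

    def resolve_pattern(self) -> TestPattern:
        return bundled_pattern(self.pattern_id)

    def resolve_archetypes(self, pattern: TestPattern) -> dict[str, list[int]]:
        archetypes = self.archetypes or default_archetypes(pattern)
        if not archetypes:
            raise ValueError("archetype set is empty")
        for name, idx in archetypes.items():
            if any(i < 0 or i >= pattern.L for i in idx):
                raise ValueError(f"archetype {name!r} has indices outside [0, {pattern.L})")
        return archetypes


_MAX_REJECT = 1000


def _background(config: SynthConfig, pattern: TestPattern, rng, offset: Optional[float]):
    if offset is None:
        offset = rng.normal(config.control_offset_mean, config.control_offset_sd)
    noise = rng.normal(0.0, config.control_noise_sd, size=pattern.L)
    return offset, offset + noise


def sample_control_vf(
    config: SynthConfig,
    rng: np.random.Generator,
    pattern: Optional[TestPattern] = None,
    subject_id: str = "C000",
    eye: str = "OD",
    offset: Optional[float] = None,
) -> VisualFieldRecord:
    """One control examination: per-eye offset + per-location noise, MD < cap."""
    pattern = pattern or config.resolve_pattern()
    for _ in range(_MAX_REJECT):
        off, deviations = _background(config, pattern, rng, offset)
        if mean_defect(deviations[pattern.usable]) < config.md_cap:
            return VisualFieldRecord(
                subject_id=subject_id, eye=eye, pattern_id=pattern.pattern_id,
                deviations=deviations, group="control", meta={"offset": off},
            )
    raise RuntimeError("rejection sampling failed to satisfy the MD cap")


def sample_eg_vf(
    config: SynthConfig,
    rng: np.random.Generator,
    pattern: Optional[TestPattern] = None,
    subject_id: str = "G000",
    eye: str = "OD",
    offset: Optional[float] = None,
    archetype: Optional[str] = None,
    depth: Optional[float] = None,
) -> VisualFieldRecord:
    """One early-glaucoma examination: control background + archetype defect.

    A focal archetype lowers only its member locations by ``depth`` dB
    (sampled from the configured depth distribution when not given); the
    diffuse archetype mildly lowers every usable location.  MD < cap is
    enforced by resampling the background/defect noise.
    """
    pattern = pattern or config.resolve_pattern()
    archetypes = config.resolve_archetypes(pattern)
    if archetype is None:
        archetype = str(rng.choice(sorted(archetypes)))
    if archetype not in archetypes:
        raise ValueError(f"unknown archetype {archetype!r}")
    idx = np.asarray(archetypes[archetype], dtype=int)
    for _ in range(_MAX_REJECT):
        off, deviations = _background(config, pattern, rng, offset)
        if depth is None:
            if archetype == "diffuse":
                d = rng.normal(config.diffuse_depth_mean, config.diffuse_depth_sd)
            else:
                d = rng.normal(config.defect_depth_mean, config.defect_depth_sd)
        else:
            d = depth
        d = max(d, 0.0)
        loss = np.zeros(pattern.L)
        loss[idx] = -d
        candidate = deviations + loss
        if mean_defect(candidate[pattern.usable]) < config.md_cap:
            return VisualFieldRecord(
                subject_id=subject_id, eye=eye, pattern_id=pattern.pattern_id,
                deviations=candidate, group="EG",
                meta={"offset": off, "archetype": archetype, "depth": d},
            )
    raise RuntimeError("rejection sampling failed to satisfy the MD cap")


def generate_dataset(
    config: SynthConfig,
) -> tuple[list[VisualFieldRecord], pd.DataFrame]:
    """A full labeled cohort plus its subject roster.

    Each subject contributes ``eyes_per_subject`` eyes with a number of
    visits drawn from ``visits_per_eye``.  Per eye, the background offset is
    persistent across visits; EG eyes keep one archetype for all visits with
    a slowly deepening focal defect (longitudinal consistency).  Fully
    deterministic under ``config.seed``.
    """
    pattern = config.resolve_pattern()
    archetypes = config.resolve_archetypes(pattern)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.visits_per_eye
    records: list[VisualFieldRecord] = []
    roster_rows = []
    groups = [("control", config.n_control_subjects, "C"), ("EG", config.n_eg_subjects, "G")]
    for group, n_subjects, prefix in groups:
        for s in range(n_subjects):
            subject_id = f"{prefix}{s + 1:03d}"
            eyes = ["OD", "OS"] if config.eyes_per_subject == 2 else [str(rng.choice(["OD", "OS"]))]
            for eye in eyes:
                n_visits = int(rng.integers(lo, hi + 1))
                offset = rng.normal(config.control_offset_mean, config.control_offset_sd)
                if group == "EG":
                    archetype = str(rng.choice(sorted(archetypes)))
                    if archetype == "diffuse":
                        base_depth = rng.normal(config.diffuse_depth_mean, config.diffuse_depth_sd)
                    else:
                        base_depth = rng.normal(config.defect_depth_mean, config.defect_depth_sd)
                    base_depth = max(base_depth, 0.0)
                else:
                    archetype, base_depth = None, 0.0
                roster_rows.append(
                    {"subject_id": subject_id, "eye": eye, "group": group,
                     "n_visits": n_visits, "archetype": archetype or "NA"}
                )
                for visit in range(n_visits):
                    if group == "control":
                        rec = sample_control_vf(
                            config, rng, pattern, subject_id=subject_id, eye=eye, offset=offset
                        )
                    else:
                        depth = base_depth + config.progression_per_visit * visit
                        rec = sample_eg_vf(
                            config, rng, pattern, subject_id=subject_id, eye=eye,
                            offset=offset, archetype=archetype, depth=depth,
                        )
                    rec.meta["visit"] = visit
                    records.append(rec)
    roster = pd.DataFrame(roster_rows)
    return records, roster


def write_dataset(config: SynthConfig, out_dir) -> tuple[Path, Path]:
    """Generate and write the VF table and roster CSVs; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, roster = generate_dataset(config)
    vf_path = out_dir / "vf_table.csv"
    roster_path = out_dir / "roster.csv"
    write_vf_table(records, vf_path)
    roster.to_csv(roster_path, index=False)
    return vf_path, roster_path
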