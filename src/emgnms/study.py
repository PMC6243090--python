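"""End-to-end calibration studies on synthetic cohorts.

`calibrate_subject` runs the whole pipeline for one subject — protocol
synthesis, train/validation split, linear and GA calibration on the
training split, three-condition evaluation — and `run_cohort_study`
repeats it over a cohort and aggregates mean +/- SD per joint and
condition, mirroring the per-subject-then-average structure of a human
validation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, build_design
from .emg import EmgConfig
from .evaluation import PerformanceReport, SplitPlan, compare_conditions, split_dataset
from .ga import GAConfig, calibrate_ga
from .gravity import default_masses
from .linear import calibrate_linear
from .muscle import default_models
from .results import FitResult
from .synthetic import NoiseConfig, SyntheticSubject, sample_subject, synthesize_dataset

__all__ = ["SubjectResult", "CohortReport", "calibrate_subject", "run_cohort_study"]

JOINTS = ("elbow", "shoulder")
CONDITIONS = ("non-optimized", "linear", "ga")


@dataclass(frozen=True)
class SubjectResult:
    subject: SyntheticSubject
    dataset: Dataset
    split: SplitPlan
    lo_fits: dict
    ga_fits: dict
    report: PerformanceReport


@dataclass(frozen=True)
class CohortReport:
    """Per-subject metrics and cohort mean +/- SD.

    metric(joint, condition, metric, split) -> per-subject array.
    """

    subjects: tuple[SubjectResult, ...]

    def metric(self, joint, condition, metric="e_rms", split="validation"):
        return np.array(
            [s.report.get(joint, condition, split)[metric] for s in self.subjects]
        )

    def summary(self) -> list[dict]:
        rows = []
        for joint in JOINTS:
            for cond in CONDITIONS:
                for metric in ("e_rms", "r2"):
                    vals = self.metric(joint, cond, metric)
                    rows.append(
                        {
                            "joint": joint,
                            "condition": cond,
                            "metric": metric,
                            "mean": float(vals.mean()),
                            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        }
                    )
        return rows


def calibrate_subject(
    subject: SyntheticSubject,
    seed: int,
    ga_config: GAConfig | None = None,
    config: EmgConfig = EmgConfig(),
    decimate: int = 48,
    run_ga: bool = True,
) -> SubjectResult:
    """Synthesise the protocol and calibrate both joints both ways."""
    rng = np.random.default_rng(seed)
    data_seed, split_seed, ga_seed = (int(x) for x in rng.integers(0, 2**31 - 1, 3))
    dataset = synthesize_dataset(subject, seed=data_seed, config=config)
    split = split_dataset(dataset, seed=split_seed)
    train = build_design(dataset, split.train_ids, config, decimate)

    defaults, default_anthro = default_models()
    M_a0, M_fh0 = default_masses(dataset.body_mass)
    anthro0 = default_anthro.with_masses(M_a=M_a0, M_fh=M_fh0)

    lo_fits: dict[str, FitResult] = {}
    ga_fits: dict[str, FitResult] = {}
    for joint in JOINTS:
        lo_fits[joint] = calibrate_linear(train, defaults[joint], anthro0)
        if run_ga:
            cfg = ga_config or GAConfig(seed=ga_seed)
            if cfg.seed != ga_seed:
                cfg = GAConfig(**{**cfg.__dict__, "seed": ga_seed})
            ga_fits[joint] = calibrate_ga(train, defaults[joint], anthro0, cfg)
    report = compare_conditions(
        dataset, split, defaults, anthro0, lo_fits, ga_fits, config, decimate
    )
    return SubjectResult(subject, dataset, split, lo_fits, ga_fits, report)


def run_cohort_study(
    n_subjects: int = 7,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    mode: str = "full",
    ga_config: GAConfig | None = None,
    decimate: int = 48,
    run_ga: bool = True,
) -> CohortReport:
    """Synthetic cohort replication of the three-condition comparison."""
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_subjects):
        subj_seed, pipe_seed = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
        subject = sample_subject(subj_seed, mode=mode, noise=noise)
        results.append(
            calibrate_subject(
                subject, seed=pipe_seed, ga_config=ga_config,
                decimate=decimate, run_ga=run_ga,
            )
        )
    return CohortReport(tuple(results))
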