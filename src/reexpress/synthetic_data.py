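"""Synthetic study tables with known ground truth.

Generates collections of simulated "studies" that mimic the statistical
structure of the packaged evaluation table — sample sizes spanning roughly
100 to 50,000 and log-exposure SDs around 0.45–1.3 — but with a known true
untransformed-scale slope built into the data-generating mechanism.  Each
study draws a lognormal exposure sample, generates the outcome in unlogged
space (``Y = beta_true * X + noise``), fits both the untransformed and the
log-exposure regressions, and fills a complete :class:`~reexpress.study_data.StudyRecord`
whose re-expressed columns come from the three default re-expression methods
with CI propagation.  Because the truth is known and constant, the full
pipeline (re-expression -> CI propagation -> membership screen) is testable
end to end, and the screen's characteristic size effect — approximation error
exposed by precise large-n observed estimates — can be reproduced at will.

Not emulated: covariate adjustment, confounding, heterogeneous outcome types,
or between-study heterogeneity in the true slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mc_engine import DegenerateDesignError, fit_slope, sample_exposure
from .reexpression import ReportedLoggedEstimate, ci_from_se, reexpress
from .study_data import StudyRecord

__all__ = ["SyntheticStudySpec", "generate_study", "generate_study_table"]


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Specification for a collection of synthetic studies.

    Default ranges mirror the empirical collection's envelope: n_obs
    log-uniform on [100, 50000], sigma uniform on [0.45, 1.3], exposure
    median log-uniform on [1, 50].
    """

    n_studies: int = 15
    n_obs_range: tuple[int, int] = (100, 50_000)
    sigma_range: tuple[float, float] = (0.45, 1.3)
    median_range: tuple[float, float] = (1.0, 50.0)
    beta_true: float = 1.0
    noise_sd: float = 1.0
    log_base: float = 10.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be at least 1")
        if self.n_obs_range[0] > self.n_obs_range[1] or self.n_obs_range[0] < 3:
            raise ValueError(f"invalid n_obs_range {self.n_obs_range}")
        if self.sigma_range[0] > self.sigma_range[1] or self.sigma_range[0] <= 0:
            raise ValueError(f"invalid sigma_range {self.sigma_range}")
        if self.median_range[0] > self.median_range[1] or self.median_range[0] <= 0:
            raise ValueError(f"invalid median_range {self.median_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.log_base > 1:
            raise ValueError("log_base must exceed 1")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")


def _study_rng(spec: SyntheticStudySpec, index: int, retry: int = 0) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index, retry])


def generate_study(
    spec: SyntheticStudySpec,
    index: int,
    rng: np.random.Generator | None = None,
) -> tuple[StudyRecord, ReportedLoggedEstimate, float]:
    """Simulate one study; returns (record, logged estimate, true slope).

    The record's observed column is the OLS fit of outcome on untransformed
    exposure with its normal-theory 95% CI; the re-expressed columns apply
    the RB/Dz/Alt factors (multiplicative CI propagation) to the study's own
    log-exposure fit, using the sample median and sample log-scale SD as the
    distributional context — exactly what a meta-analyst extracting from the
    published study would have.
    """
    if index >= spec.n_studies:
        raise IndexError(f"index {index} out of range for {spec.n_studies} studies")

    for retry in range(100):
        gen = rng if rng is not None else _study_rng(spec, index, retry)
        lo, hi = spec.n_obs_range
        n_obs = int(round(math.exp(gen.uniform(math.log(lo), math.log(hi)))))
        n_obs = min(max(n_obs, lo), hi)
        sigma = float(gen.uniform(*spec.sigma_range))
        median = float(math.exp(gen.uniform(*map(math.log, spec.median_range))))

        x = sample_exposure(n_obs, median, sigma, spec.log_base, gen)
        noise = gen.normal(0.0, spec.noise_sd, n_obs) if spec.noise_sd > 0 else 0.0
        y = spec.beta_true * x + noise
        log_x = np.log(x) / math.log(spec.log_base)
        try:
            beta_obs, se_obs = fit_slope(x, y)
            beta_log, se_log = fit_slope(log_x, y)
            break
        except DegenerateDesignError:
            if rng is not None:
                raise
    else:
        raise DegenerateDesignError(f"study {index}: degenerate design after 100 redraws")

    reported = ReportedLoggedEstimate(
        beta_log=beta_log,
        se_log=se_log,
        log_base=spec.log_base,
        geo_median=float(np.median(x)),
        sigma_log=float(np.std(log_x, ddof=1)),
    )
    reexpressed = {m: reexpress(reported, m) for m in ("RB", "Dz", "Alt")}
    record = StudyRecord(
        study_id=f"synth{index:04d}",
        author_year=f"Synthetic {index}",
        beta_observed=beta_obs,
        ci_observed=ci_from_se(beta_obs, se_obs),
        beta_rb=reexpressed["RB"].beta,
        ci_rb=reexpressed["RB"].ci,
        beta_dz=reexpressed["Dz"].beta,
        ci_dz=reexpressed["Dz"].ci,
        beta_alt=reexpressed["Alt"].beta,
        ci_alt=reexpressed["Alt"].ci,
        sigma_hat=reported.sigma_log,
        n_obs=n_obs,
        comments="synthetic",
    )
    return record, reported, spec.beta_true


def generate_study_table(
    spec: SyntheticStudySpec,
) -> tuple[list[StudyRecord], list[float]]:
    """Generate the full synthetic collection and its ground-truth slopes."""
    records, truths = [], []
    for i in range(spec.n_studies):
        record, _, truth = generate_study(spec, i)
        records.append(record)
        truths.append(truth)
    return records, truths
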