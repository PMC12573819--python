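"""Interval-membership consistency screen across studies.

For each study the screen asks: does the observed (untransformed-exposure)
estimate lie inside the 95% CI of each re-expressed estimate?  A point
comparison of two estimates ignores their sampling variability; the membership
screen is the minimal variability-aware alternative.  Studies are stratified
by sample size because a very large study pins down the observed estimate so
precisely that even small approximation error in a re-expression method is
exposed — the screen's characteristic finding is that failures concentrate
above roughly n = 5,000.

Comparisons are made on the table values verbatim (closed intervals, no
re-rounding).  Cells where the verdict is within one unit in the last printed
digit of a CI endpoint are flagged "borderline" in the rendered report, to be
transparent about rounding sensitivity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .study_data import Interval, StudyRecord

__all__ = [
    "MembershipRow",
    "ConsistencySummary",
    "contains",
    "membership_table",
    "summarize_consistency",
    "render_augmented_table",
    "DEFAULT_SIZE_THRESHOLD",
]

#: sample size above which a study counts as "very large"
DEFAULT_SIZE_THRESHOLD = 5000

SizeClass = Literal["small_moderate", "very_large"]


@dataclass(frozen=True)
class MembershipRow:
    """Per-study membership flags for the three re-expression methods."""

    study_id: str
    in_rb: bool
    in_dz: bool
    in_alt: bool
    n_obs: int
    size_class: SizeClass

    @property
    def all_consistent(self) -> bool:
        return self.in_rb and self.in_dz and self.in_alt

    @property
    def n_failures(self) -> int:
        return sum(not flag for flag in (self.in_rb, self.in_dz, self.in_alt))


@dataclass(frozen=True)
class ConsistencySummary:
    """Headline counts of the consistency screen."""

    n_studies: int
    n_very_large: int
    n_very_large_all_consistent: int
    n_small_moderate: int
    n_small_moderate_exception_cells: int


def contains(interval: Interval, x: float) -> bool:
    """Closed-interval membership: true iff ``lower <= x <= upper``."""
    return interval.contains(x)


def membership_table(
    records: Sequence[StudyRecord],
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
) -> list[MembershipRow]:
    """Evaluate the membership screen for every study, in input order."""
    rows = []
    for rec in records:
        size_class: SizeClass = (
            "very_large" if rec.n_obs > size_threshold else "small_moderate"
        )
        rows.append(
            MembershipRow(
                study_id=rec.study_id,
                in_rb=contains(rec.ci_rb, rec.beta_observed),
                in_dz=contains(rec.ci_dz, rec.beta_observed),
                in_alt=contains(rec.ci_alt, rec.beta_observed),
                n_obs=rec.n_obs,
                size_class=size_class,
            )
        )
    return rows


def summarize_consistency(rows: Sequence[MembershipRow]) -> ConsistencySummary:
    """Headline counts; a study is "consistent" iff all three flags are true."""
    if not rows:
        raise ValueError("cannot summarize an empty membership table")
    very_large = [r for r in rows if r.size_class == "very_large"]
    small = [r for r in rows if r.size_class == "small_moderate"]
    return ConsistencySummary(
        n_studies=len(rows),
        n_very_large=len(very_large),
        n_very_large_all_consistent=sum(r.all_consistent for r in very_large),
        n_small_moderate=len(small),
        n_small_moderate_exception_cells=sum(r.n_failures for r in small),
    )


def _printed_ulp(x: float) -> float:
    """One unit in the last printed decimal digit of ``x``.

    Uses the shortest round-tripping decimal representation, which equals the
    printed form for values stored verbatim from a printed table.
    """
    text = repr(float(x))
    if "e" in text or "E" in text:
        mantissa, exponent = re.split("[eE]", text)
        frac = len(mantissa.split(".")[1]) if "." in mantissa else 0
        return 10.0 ** (int(exponent) - frac)
    frac = len(text.split(".")[1]) if "." in text else 0
    return 10.0**-frac


def _borderline(interval: Interval, x: float) -> bool:
    """True if membership could flip within one unit of an endpoint's last digit."""
    return (
        abs(x - interval.lower) <= _printed_ulp(interval.lower)
        or abs(x - interval.upper) <= _printed_ulp(interval.upper)
    )


def _fmt_est(beta: float, ci: Interval) -> str:
    return f"{beta!r} ({ci.lower!r}, {ci.upper!r})"


def render_augmented_table(
    records: Sequence[StudyRecord],
    rows: Sequence[MembershipRow],
    path: str | Path,
) -> pd.DataFrame:
    """Write the augmented report: estimates with CIs, Y/N flags, sigma, n_obs.

    ``records`` and ``rows`` must be aligned by study_id in the same order.
    Returns the report frame (also written to ``path`` as CSV).
    """
    if [r.study_id for r in records] != [m.study_id for m in rows]:
        raise ValueError("records and membership rows are misaligned by study_id")

    def flag(member: bool, borderline: bool) -> str:
        text = "Y" if member else "N"
        return text + "*" if borderline else text

    out = []
    for rec, mem in zip(records, rows):
        out.append(
            {
                "study_id": rec.study_id,
                "author_year": rec.author_year,
                "beta_observed": _fmt_est(rec.beta_observed, rec.ci_observed),
                "beta_rb": _fmt_est(rec.beta_rb, rec.ci_rb),
                "beta_dz": _fmt_est(rec.beta_dz, rec.ci_dz),
                "beta_alt": _fmt_est(rec.beta_alt, rec.ci_alt),
                "in_rb": flag(mem.in_rb, _borderline(rec.ci_rb, rec.beta_observed)),
                "in_dz": flag(mem.in_dz, _borderline(rec.ci_dz, rec.beta_observed)),
                "in_alt": flag(mem.in_alt, _borderline(rec.ci_alt, rec.beta_observed)),
                "sigma_hat": rec.sigma_hat,
                "n_obs": rec.n_obs,
                "size_class": mem.size_class,
            }
        )
    frame = pd.DataFrame(out)
    frame.to_csv(path, index=False)
    return frame
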