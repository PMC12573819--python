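"""Study evaluation tables: typed records, validation, and CSV I/O.

The central object is a :class:`StudyRecord` — one study's observed
(untransformed-exposure) regression coefficient with its 95% CI, three
re-expressed coefficients (methods RB, Dz, Alt) each with a 95% CI, the
estimated SD of the log-transformed exposure (``sigma_hat``), and the study
sample size.  A 15-study evaluation table compiled from the published
environmental-epidemiology literature ships with the package as a verbatim
fixture (:func:`fixture_path`); suspected typographical quirks of the printed
source are preserved and annotated in a ``comments`` column rather than
silently corrected.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "Interval",
    "StudyRecord",
    "SchemaError",
    "TableParseError",
    "ValidationError",
    "read_study_table",
    "write_study_table",
    "fixture_path",
    "load_fixture",
    "FIXTURE_SHA256",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class TableParseError(ValueError):
    """A cell could not be parsed as a number."""


class ValidationError(ValueError):
    """A record violates a structural invariant."""


# sha256 of the packaged evaluation-table fixture, committed alongside it so
# accidental edits are caught by the test suite.
FIXTURE_SHA256 = "5ace02dd1dfec46bd51c08687fbd321c90f945cb645b92176485fe2a7a34238b"


@dataclass(frozen=True, order=True)
class Interval:
    """A closed real interval, typically a two-sided confidence interval.

    The constructor reorders the endpoints so ``lower <= upper`` always
    holds.  NaN endpoints are rejected; infinite endpoints are permitted
    (degenerate intervals are occasionally useful in testing).
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        lo, hi = float(self.lower), float(self.upper)
        if math.isnan(lo) or math.isnan(hi):
            raise ValidationError("interval endpoints must not be NaN")
        if lo > hi:
            lo, hi = hi, lo
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        """Closed-interval membership: ``lower <= x <= upper``."""
        return self.lower <= x <= self.upper

    def scaled(self, k: float) -> "Interval":
        """Multiply both endpoints by ``k`` (reordered automatically)."""
        return Interval(k * self.lower, k * self.upper)


#: re-expression method labels, in the column order of the evaluation table
METHODS = ("rb", "dz", "alt")


@dataclass(frozen=True)
class StudyRecord:
    """One row of a study evaluation table."""

    study_id: str
    author_year: str
    beta_observed: float
    ci_observed: Interval
    beta_rb: float
    ci_rb: Interval
    beta_dz: float
    ci_dz: Interval
    beta_alt: float
    ci_alt: Interval
    sigma_hat: float
    n_obs: int
    comments: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be nonempty")
        if not (self.sigma_hat > 0):
            raise ValidationError(
                f"{self.study_id}: sigma_hat must be positive, got {self.sigma_hat}"
            )
        if self.n_obs < 3:
            raise ValidationError(
                f"{self.study_id}: n_obs must be at least 3, got {self.n_obs}"
            )
        for name, beta, ci in self.estimates():
            if not ci.contains(beta):
                raise ValidationError(
                    f"{self.study_id}: beta_{name}={beta} lies outside its CI "
                    f"({ci.lower}, {ci.upper})"
                )

    def estimates(self):
        """Yield ``(label, beta, ci)`` for the observed and re-expressed columns."""
        yield "observed", self.beta_observed, self.ci_observed
        yield "rb", self.beta_rb, self.ci_rb
        yield "dz", self.beta_dz, self.ci_dz
        yield "alt", self.beta_alt, self.ci_alt


# Canonical CSV column names.  A user-supplied ``dialect`` maps these
# canonical names onto the actual header of their extraction sheet.
_COLUMNS = [
    "study_id",
    "author_year",
    "beta_observed",
    "ci_observed_lower",
    "ci_observed_upper",
    "beta_rb",
    "ci_rb_lower",
    "ci_rb_upper",
    "beta_dz",
    "ci_dz_lower",
    "ci_dz_upper",
    "beta_alt",
    "ci_alt_lower",
    "ci_alt_upper",
    "sigma_hat",
    "n_obs",
]
_OPTIONAL_COLUMNS = ["comments"]

# Typography found in published tables: Unicode minus signs and thin/no-break
# spaces must be normalised before numeric parsing.
_NUMERIC_TRANSLATION = str.maketrans(
    {
        "−": "-",  # minus sign
        "‐": "-",  # hyphen
        "‑": "-",  # non-breaking hyphen
        "–": "-",  # en dash (seen in CI ranges)
        " ": "",  # thin space
        " ": "",  # narrow no-break space
        " ": "",  # no-break space
        ",": "",  # thousands separator, e.g. 46,294
        " ": "",
    }
)


def normalize_numeric_text(text: str) -> str:
    """Normalise Unicode minus variants and spacing in a numeric cell."""
    return text.translate(_NUMERIC_TRANSLATION)


def _parse_number(cell, column: str, row_index: int) -> float:
    if isinstance(cell, (int, float)) and not isinstance(cell, bool):
        value = float(cell)
    else:
        try:
            value = float(normalize_numeric_text(str(cell)))
        except (TypeError, ValueError):
            raise TableParseError(
                f"row {row_index}: cannot parse column {column!r} value {cell!r} "
                "as a number"
            ) from None
    if math.isnan(value):
        raise TableParseError(f"row {row_index}: column {column!r} is missing/NaN")
    return value


def read_study_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[StudyRecord]:
    """Read a study evaluation table from delimited text.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8).
    dialect
        Optional mapping from canonical column names (``beta_observed``,
        ``ci_rb_lower``, ...) to the column names actually present, for
        loading user extraction sheets without renaming.

    Returns
    -------
    list of StudyRecord, one per data row, in file order, fully validated.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)

    def actual(name: str) -> str:
        return dialect.get(name, name)

    missing = [c for c in _COLUMNS if actual(c) not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))

        def num(name: str) -> float:
            return _parse_number(row[actual(name)], actual(name), i)

        study_id = str(row[actual("study_id")]).strip()
        if study_id in seen_ids:
            raise ValidationError(f"duplicate study_id {study_id!r}")
        seen_ids.add(study_id)

        n_obs_value = num("n_obs")
        if n_obs_value != int(n_obs_value):
            raise TableParseError(f"row {i}: n_obs must be an integer")

        comments_col = actual("comments")
        record = StudyRecord(
            study_id=study_id,
            author_year=str(row[actual("author_year")]).strip(),
            beta_observed=num("beta_observed"),
            ci_observed=Interval(num("ci_observed_lower"), num("ci_observed_upper")),
            beta_rb=num("beta_rb"),
            ci_rb=Interval(num("ci_rb_lower"), num("ci_rb_upper")),
            beta_dz=num("beta_dz"),
            ci_dz=Interval(num("ci_dz_lower"), num("ci_dz_upper")),
            beta_alt=num("beta_alt"),
            ci_alt=Interval(num("ci_alt_lower"), num("ci_alt_upper")),
            sigma_hat=num("sigma_hat"),
            n_obs=int(n_obs_value),
            comments=str(row.get(comments_col, "")),
        )
        records.append(record)
    return records


def _format_number(x: float) -> str:
    # repr() gives the shortest decimal string that round-trips, which both
    # preserves full precision and keeps printed fixture values as printed.
    if x == int(x) and abs(x) < 1e15:
        return str(int(x)) if float(int(x)) == x else repr(x)
    return repr(x)


def write_study_table(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write records as canonical CSV; round-trips through :func:`read_study_table`."""
    rows = []
    for rec in records:
        rec.validate()
        rows.append(
            {
                "study_id": rec.study_id,
                "author_year": rec.author_year,
                "beta_observed": _format_number(rec.beta_observed),
                "ci_observed_lower": _format_number(rec.ci_observed.lower),
                "ci_observed_upper": _format_number(rec.ci_observed.upper),
                "beta_rb": _format_number(rec.beta_rb),
                "ci_rb_lower": _format_number(rec.ci_rb.lower),
                "ci_rb_upper": _format_number(rec.ci_rb.upper),
                "beta_dz": _format_number(rec.beta_dz),
                "ci_dz_lower": _format_number(rec.ci_dz.lower),
                "ci_dz_upper": _format_number(rec.ci_dz.upper),
                "beta_alt": _format_number(rec.beta_alt),
                "ci_alt_lower": _format_number(rec.ci_alt.lower),
                "ci_alt_upper": _format_number(rec.ci_alt.upper),
                "sigma_hat": _format_number(rec.sigma_hat),
                "n_obs": str(rec.n_obs),
                "comments": rec.comments,
            }
        )
    frame = pd.DataFrame(rows, columns=_COLUMNS + _OPTIONAL_COLUMNS)
    frame.to_csv(path, index=False)


def fixture_path() -> Path:
    """Path of the packaged 15-study evaluation-table fixture."""
    return Path(resources.files("reexpress").joinpath("data/table1_letter.csv"))


def load_fixture() -> list[StudyRecord]:
    """Load the packaged 15-study evaluation table."""
    return read_study_table(fixture_path())
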