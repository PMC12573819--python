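"""High-level entry points with run manifests.

Each function here corresponds to one analysis a user would run end to end:

- :func:`evaluate` — consistency screen on a study table, with headline counts;
- :func:`simulate` — the variability scenario grid (percentile summaries);
- :func:`coverage` — constant-target coverage under a chosen DGM;
- :func:`stability` — sampling SD vs Monte Carlo error across iteration counts;
- :func:`generate` — synthetic study table with ground truth.

Every call that writes an output file writes a JSON *manifest* beside it
(``<output>.manifest.json``) capturing the entry point, the fully resolved
configuration (defaults included — notably ``noise_sd``, a hidden determinant
of every variability magnitude), the seed, and library versions.
:func:`rerun_from_manifest` re-executes a manifest and reproduces the output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .ci_eval import (
    DEFAULT_SIZE_THRESHOLD,
    ConsistencySummary,
    membership_table,
    render_augmented_table,
    summarize_consistency,
)
from .mc_engine import DGMConfig, coverage_vs_constant, mc_stability, run_mc, variability_grid
from .study_data import read_study_table, write_study_table
from .synthetic_data import SyntheticStudySpec, generate_study_table

__all__ = [
    "RunManifest",
    "evaluate",
    "simulate",
    "coverage",
    "stability",
    "generate",
    "rerun_from_manifest",
]


@dataclass(frozen=True)
class RunManifest:
    subcommand: str
    config: dict
    seed: int | None
    versions: dict
    timestamp: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _manifest(subcommand: str, config: dict, seed: int | None) -> RunManifest:
    return RunManifest(
        subcommand=subcommand,
        config=config,
        seed=seed,
        versions={
            "python": sys.version.split()[0],
            "reexpress": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def _emit(frame_writer, out: str | Path | None, subcommand: str,
          config: dict, seed: int | None):
    if out is None:
        return
    out = Path(out)
    frame_writer(out)
    _manifest(subcommand, config, seed).write(out.with_suffix(out.suffix + ".manifest.json"))


def evaluate(
    table: str | Path,
    threshold: int = DEFAULT_SIZE_THRESHOLD,
    out: str | Path | None = None,
) -> ConsistencySummary:
    """Run the consistency screen on a study table; optionally write the report."""
    records = read_study_table(table)
    rows = membership_table(records, size_threshold=threshold)
    summary = summarize_consistency(rows)
    if out is not None:
        render_augmented_table(records, rows, out)
        _manifest("evaluate", {"table": str(table), "threshold": threshold}, None).write(
            Path(out).with_suffix(Path(out).suffix + ".manifest.json")
        )
    return summary


def simulate(
    n_obs_values=(162, 8474),
    sigmas=(0.25, 0.45, 0.65, 0.85),
    space: str = "logged",
    noise_sd: float = 1.0,
    n_sims: int = 2000,
    seed: int = 1,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Run the variability scenario grid; one summary row per (n_obs, sigma)."""
    grid = variability_grid(n_obs_values, sigmas, space=space,
                            noise_sd=noise_sd, n_sims=n_sims, seed=seed)
    config = {
        "n_obs_values": list(map(int, n_obs_values)),
        "sigmas": list(map(float, sigmas)),
        "space": space, "noise_sd": noise_sd, "n_sims": n_sims,
    }
    _emit(lambda p: grid.to_csv(p, index=False), out, "simulate", config, seed)
    return grid


def coverage(
    n_obs: int = 162,
    sigma: float = 0.45,
    space: str = "unlogged",
    noise_sd: float = 1.0,
    n_sims: int = 2000,
    seed: int = 1,
    level: float = 0.95,
    out: str | Path | None = None,
):
    """Coverage of the constant true slope by the estimand's per-iteration CIs."""
    config = DGMConfig(n_obs=n_obs, sigma=sigma, space=space, noise_sd=noise_sd,
                       n_sims=n_sims, seed=seed, level=level)
    result = coverage_vs_constant(run_mc(config), scale="estimand")
    frame = pd.DataFrame([dataclasses.asdict(result)])
    _emit(lambda p: frame.to_csv(p, index=False), out, "coverage",
          {"n_obs": n_obs, "sigma": sigma, "space": space, "noise_sd": noise_sd,
           "n_sims": n_sims, "level": level}, seed)
    return result


def stability(
    n_obs: int = 162,
    sigma: float = 0.25,
    space: str = "logged",
    noise_sd: float = 1.0,
    sim_counts=(500, 2000),
    seed: int = 1,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Sampling SD plateau vs shrinking MC standard error of the mean."""
    config = DGMConfig(n_obs=n_obs, sigma=sigma, space=space, noise_sd=noise_sd,
                       n_sims=max(sim_counts), seed=seed)
    frame = mc_stability(config, list(sim_counts))
    _emit(lambda p: frame.to_csv(p, index=False), out, "stability",
          {"n_obs": n_obs, "sigma": sigma, "space": space, "noise_sd": noise_sd,
           "sim_counts": list(map(int, sim_counts))}, seed)
    return frame


def generate(
    n_studies: int = 15,
    seed: int = 1,
    out: str | Path | None = None,
    **spec_kwargs,
):
    """Generate a synthetic study table; truths go to a ``*.truths.csv`` sidecar."""
    spec = SyntheticStudySpec(n_studies=n_studies, seed=seed, **spec_kwargs)
    records, truths = generate_study_table(spec)
    if out is not None:
        out = Path(out)
        write_study_table(records, out)
        truths_path = out.with_suffix(".truths.csv")
        pd.DataFrame(
            {"study_id": [r.study_id for r in records], "beta_true": truths}
        ).to_csv(truths_path, index=False)
        _manifest("generate", dataclasses.asdict(spec), seed).write(
            out.with_suffix(out.suffix + ".manifest.json")
        )
    return records, truths


_SUBCOMMANDS = {
    "evaluate": evaluate,
    "simulate": simulate,
    "coverage": coverage,
    "stability": stability,
    "generate": generate,
}


def rerun_from_manifest(manifest_path: str | Path, out: str | Path):
    """Re-execute the run a manifest describes, writing output to ``out``.

    Given identical library versions, the output reproduces the original byte
    for byte (the manifest's own timestamp differs, of course).
    """
    spec = json.loads(Path(manifest_path).read_text())
    name = spec["subcommand"]
    if name not in _SUBCOMMANDS:
        raise ValueError(f"unknown subcommand {name!r} in manifest")
    config = dict(spec["config"])
    if name == "generate":
        for key in ("n_obs_range", "sigma_range", "median_range"):
            if key in config:
                config[key] = tuple(config[key])
        config.pop("seed", None)
    if spec["seed"] is not None:
        config["seed"] = spec["seed"]
    return _SUBCOMMANDS[name](**config, out=out)
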