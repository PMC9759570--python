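"""Tidy CSV formats tying the pipeline stages together.

Time courses travel as long-format CSV with explicit units in the column
names (animal_id, group, analyte, time_h, concentration_ng_ml, and an
optional below_loq flag); feature tables are one row per animal.  Every
writer's output is re-readable by the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import CredibilityBand, PosteriorEnsemble
from .fitting import ConcentrationSeries

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_features",
    "write_features",
    "write_ensemble",
    "read_ensemble",
    "write_band",
]

TIMECOURSE_COLUMNS = ("animal_id", "group", "analyte", "time_h", "concentration_ng_ml")


def read_timecourses(path) -> list[ConcentrationSeries]:
    """Read a tidy time-course CSV into per-replicate series.

    Rows are grouped by (animal, analyte) and sorted by time; schema and
    invariant violations raise with the offending row named.
    """
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    neg = df.index[df["time_h"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative time_h at row {int(neg[0]) + 2}")  # 1-based + header
    series = []
    for (animal, analyte), sub in df.groupby(["animal_id", "analyte"], sort=True):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: duplicated time points for {animal}/{analyte}")
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"{path}: inconsistent group labels for {animal}/{analyte}")
        below = sub["below_loq"].to_numpy(dtype=bool) if "below_loq" in sub else None
        series.append(ConcentrationSeries(
            animal_id=str(animal), group=str(groups[0]), analyte=str(analyte),
            times=times,
            concentrations=sub["concentration_ng_ml"].to_numpy(dtype=float),
            below_loq=below))
    return series


def write_timecourses(series: list[ConcentrationSeries], path) -> None:
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "animal_id": s.animal_id,
            "group": s.group,
            "analyte": s.analyte,
            "time_h": s.times,
            "concentration_ng_ml": s.concentrations,
            "below_loq": s.below_loq,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("animal_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def write_ensemble(ensemble: PosteriorEnsemble, csv_path, meta_path=None) -> None:
    """Posterior draws as CSV plus a JSON sidecar with chain metadata."""
    pd.DataFrame(ensemble.samples, columns=["A", "B", "sigma"]).to_csv(
        csv_path, index=False)
    if meta_path is not None:
        meta = {
            "n_chains": ensemble.n_chains,
            "n_samples_requested": ensemble.n_samples_requested,
            "burn_in_index": ensemble.burn_in_index,
            "ess": list(map(float, np.atleast_1d(ensemble.ess))),
            "seed": ensemble.seed,
            "acceptance_rate": ensemble.acceptance_rate,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_ensemble(csv_path, meta_path) -> PosteriorEnsemble:
    samples = pd.read_csv(csv_path)[["A", "B", "sigma"]].to_numpy(dtype=float)
    meta = json.loads(Path(meta_path).read_text())
    return PosteriorEnsemble(
        samples=samples, n_chains=meta["n_chains"],
        n_samples_requested=meta["n_samples_requested"],
        burn_in_index=meta["burn_in_index"],
        ess=np.asarray(meta["ess"], dtype=float), seed=meta["seed"],
        acceptance_rate=meta.get("acceptance_rate", float("nan")))


def write_band(band: CredibilityBand, path) -> None:
    pd.DataFrame({
        "time_h": band.time_grid,
        "lower_ng_ml": band.lower,
        "center_ng_ml": band.center,
        "upper_ng_ml": band.upper,
    }).to_csv(path, index=False)
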