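"""Synthetic study data calibrated to the printed group summaries.

Emulates the measurements of the periportal-steatosis mouse study so the
whole pipeline is testable without the animal data: drug-cocktail time
courses at the ten scheduled sampling times over six hours (pre-dose,
0.25, 0.5, 1, 1.5, 2, 2.5, 3, 4, 6 h) for three groups (control, 2-week
and 4-week high-fat diet), with additive Gaussian measurement noise, and
group-structured per-animal features (steatosis surfaces, hepatic
triglycerides, ex-vivo CYP activities) drawn from truncated normals whose
means and SDs are the printed group summaries.

The truncated normals are moment-matched: the underlying location is
solved so that the *truncated* mean equals the configured mean (the scale
stays at the configured SD), keeping the calibration exact even where a
bound sits within a few SD of the mean (e.g. control TG at 99.6 +/- 42.3
with a hard floor at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .fitting import ConcentrationSeries
from .model import PKParams, evaluate_curve, peak_concentration
from .steatosis import MIN_TILES, SteatosisSurfaces, TileGrid

__all__ = [
    "GROUPS",
    "ANALYTES",
    "DEFAULT_TIME_GRID",
    "SynthConfig",
    "default_config",
    "generate_features",
    "generate_timecourses",
    "generate_tile_grid",
    "fixture_fig10",
]

GROUPS = ("control", "hfd_2wk", "hfd_4wk")
ANALYTES = ("caffeine", "midazolam", "codeine")

# ten scheduled sampling times over six hours
DEFAULT_TIME_GRID = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0)

FEATURES = (
    "lipid_droplet_pct",
    "micro_pct",
    "macro_pct",
    "tg_nmol_per_100mg",
    "cyp3a_pmol_min_mg",
    "cyp1a_pmol_min_mg",
    "cyp2e1_pmol_min_mg",
)

PCT_BOUNDS = (0.0, 100.0)
POS_BOUNDS = (0.0, np.inf)

FEATURE_BOUNDS = {
    "lipid_droplet_pct": PCT_BOUNDS,
    "micro_pct": PCT_BOUNDS,
    "macro_pct": PCT_BOUNDS,
    "tg_nmol_per_100mg": POS_BOUNDS,
    "cyp3a_pmol_min_mg": POS_BOUNDS,
    "cyp1a_pmol_min_mg": POS_BOUNDS,
    "cyp2e1_pmol_min_mg": POS_BOUNDS,
}


@dataclass
class SynthConfig:
    """Study-condition configuration of the generators.

    ``feature_specs`` maps group -> feature -> (mean, sd); ``pk_truth``
    maps group -> analyte -> PKParams; ``noise_sigma`` is the additive
    measurement-noise SD per analyte (ng/ml); ``loq`` the per-analyte
    limit of quantification (ng/ml).
    """

    feature_specs: dict[str, dict[str, tuple[float, float]]]
    pk_truth: dict[str, dict[str, PKParams]]
    noise_sigma: dict[str, float]
    loq: dict[str, float]
    n_per_group: int = 6
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID

    def __post_init__(self) -> None:
        for g, specs in self.feature_specs.items():
            for f, (m, s) in specs.items():
                if s < 0:
                    raise ValueError(f"SD must be >= 0 for {g}/{f}")
        for g, per_analyte in self.pk_truth.items():
            for a, p in per_analyte.items():
                if not (0 < p.A < 100 and 0 < p.B < 100):
                    raise ValueError(f"PK truth for {g}/{a} outside the prior box")
        if any(s < 0 for s in self.noise_sigma.values()):
            raise ValueError("noise sigma must be >= 0")


def default_config() -> SynthConfig:
    """Defaults calibrated to the printed group summaries.

    Steatosis surfaces and TG use the printed means +/- SD; control
    steatosis surfaces default to small positive values (1 +/- 0.5%) to
    avoid degenerate zero-variance columns.  CYP activities have no
    printed group means, so plausible assay-scale defaults reproduce the
    reported direction of effects (CYP3A/CYP1A down, CYP2E1 up with
    steatosis).  Curve parameters keep the peak within 15-60 min and
    elimination within 4-6 h; noise SDs give ~10% CV at the control peak.
    """
    feature_specs = {
        "control": {
            "lipid_droplet_pct": (1.0, 0.5),
            "micro_pct": (1.0, 0.5),
            "macro_pct": (1.0, 0.5),
            "tg_nmol_per_100mg": (99.6, 42.3),
            "cyp3a_pmol_min_mg": (80.0, 20.0),
            "cyp1a_pmol_min_mg": (120.0, 30.0),
            "cyp2e1_pmol_min_mg": (50.0, 15.0),
        },
        "hfd_2wk": {
            "lipid_droplet_pct": (9.3, 1.3),
            "micro_pct": (48.6, 12.9),
            "macro_pct": (20.7, 7.1),
            "tg_nmol_per_100mg": (252.8, 43.0),
            "cyp3a_pmol_min_mg": (65.0, 18.0),
            "cyp1a_pmol_min_mg": (100.0, 25.0),
            "cyp2e1_pmol_min_mg": (75.0, 20.0),
        },
        "hfd_4wk": {
            "lipid_droplet_pct": (13.9, 2.7),
            "micro_pct": (33.4, 10.2),
            "macro_pct": (39.9, 8.6),
            "tg_nmol_per_100mg": (296.1, 91.6),
            "cyp3a_pmol_min_mg": (55.0, 15.0),
            "cyp1a_pmol_min_mg": (70.0, 20.0),
            "cyp2e1_pmol_min_mg": (95.0, 25.0),
        },
    }
    control = {
        "caffeine": PKParams(A=1.2, B=8.0),
        "midazolam": PKParams(A=2.5, B=5.0),
        "codeine": PKParams(A=2.0, B=6.0),
    }
    # caffeine elimination accelerates with microvesicular steatosis;
    # midazolam elimination slows with macrovesicular steatosis
    pk_truth = {
        "control": control,
        "hfd_2wk": {
            "caffeine": replace(control["caffeine"], A=control["caffeine"].A * 1.3),
            "midazolam": replace(control["midazolam"], A=control["midazolam"].A * 0.9),
            "codeine": replace(control["codeine"], A=control["codeine"].A * 0.95),
        },
        "hfd_4wk": {
            "caffeine": replace(control["caffeine"], A=control["caffeine"].A * 1.1),
            "midazolam": replace(control["midazolam"], A=control["midazolam"].A * 0.75),
            "codeine": replace(control["codeine"], A=control["codeine"].A * 0.9),
        },
    }
    noise_sigma = {a: round(0.1 * peak_concentration(control[a]), 1) for a in ANALYTES}
    loq = {"caffeine": 10.0, "midazolam": 1.0, "codeine": 1.0}
    return SynthConfig(feature_specs=feature_specs, pk_truth=pk_truth,
                       noise_sigma=noise_sigma, loq=loq)


def _matched_truncnorm(mean: float, sd: float, bounds: tuple[float, float]):
    """Truncated normal whose truncated mean equals ``mean`` (scale = sd)."""
    lo, hi = bounds
    if sd == 0:
        return None  # degenerate: caller emits constants

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(sps.truncnorm.mean(a, b, loc=mu, scale=sd))

    # no matching needed when the bounds are far from the mass
    if (lo == -np.inf or (mean - lo) / sd > 8) and (hi == np.inf or (hi - mean) / sd > 8):
        mu = mean
    else:
        mu = brentq(lambda m: trunc_mean(m) - mean, mean - 10 * sd, mean + 10 * sd,
                    xtol=1e-10 * max(sd, 1.0))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return sps.truncnorm(a, b, loc=mu, scale=sd)


def generate_features(config: SynthConfig, n_per_group: int | None = None,
                      seed: int = 0,
                      correlation: np.ndarray | None = None) -> pd.DataFrame:
    """Per-animal feature table drawn from the configured group summaries.

    Features are moment-matched truncated normals within their valid
    ranges.  ``correlation`` (a positive-definite matrix over the feature
    columns) optionally induces cross-feature association through a
    Gaussian copula applied within each group.
    """
    if n_per_group is None:
        n_per_group = config.n_per_group
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    feature_names = list(next(iter(config.feature_specs.values())).keys())
    k = len(feature_names)
    chol = None
    if correlation is not None:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc

    rows = {"animal_id": [], "group": []}
    cols: dict[str, list[np.ndarray]] = {f: [] for f in feature_names}
    for group in config.feature_specs:
        rows["animal_id"].extend(f"{group}_{i + 1:05d}" for i in range(n_per_group))
        rows["group"].extend([group] * n_per_group)
        if chol is not None:
            z = rng.standard_normal((n_per_group, k)) @ chol.T
            u = sps.norm.cdf(z)
        for j, feat in enumerate(feature_names):
            mean, sd = config.feature_specs[group][feat]
            bounds = FEATURE_BOUNDS.get(feat, POS_BOUNDS)
            dist = _matched_truncnorm(mean, sd, bounds)
            if dist is None:
                draws = np.full(n_per_group, mean)
            elif chol is not None:
                draws = dist.ppf(u[:, j])
            else:
                draws = dist.rvs(size=n_per_group, random_state=rng)
            cols[feat].append(draws)
    data = {**rows, **{f: np.concatenate(v) for f, v in cols.items()}}
    return pd.DataFrame(data)


def generate_timecourses(config: SynthConfig, seed: int = 0,
                         n_per_group: int | None = None) -> list[ConcentrationSeries]:
    """Noisy drug-cocktail time courses for every animal x analyte.

    Concentrations are the elimination curve at the scheduled times plus
    additive Gaussian noise, clamped at zero; the pre-dose sample is
    exactly zero and post-dose values under the analyte's LOQ are
    flagged.  Deterministic given ``seed``.
    """
    if n_per_group is None:
        n_per_group = config.n_per_group
    rng = np.random.default_rng(seed)
    t = np.asarray(config.time_grid, dtype=float)
    series: list[ConcentrationSeries] = []
    for group, per_analyte in config.pk_truth.items():
        for i in range(n_per_group):
            for analyte, params in per_analyte.items():
                sigma = config.noise_sigma[analyte]
                c = evaluate_curve(t, params)
                if sigma > 0:
                    c = c + rng.normal(0.0, sigma, size=t.shape)
                c = np.maximum(c, 0.0)
                c[t == 0] = 0.0
                series.append(ConcentrationSeries(
                    animal_id=f"{group}_{i + 1:05d}", group=group,
                    analyte=analyte, times=t, concentrations=c,
                    loq=config.loq.get(analyte)))
    return series


def generate_tile_grid(surfaces: SteatosisSurfaces, n_tiles: int,
                       seed: int = 0, lumen_fraction: float = 0.1) -> TileGrid:
    """Multinomial tile labels matching the requested surface percentages.

    Tissue-tile label probabilities follow the requested micro/macro
    shares; a ``lumen_fraction`` of tiles is vessel lumen.  Aggregating
    the output converges to the input surfaces as ``n_tiles`` grows.
    """
    if n_tiles < MIN_TILES:
        raise ValueError(f"need at least {MIN_TILES} tiles")
    if surfaces.micro_pct + surfaces.macro_pct > 100:
        raise ValueError("surfaces must sum to at most 100%")
    if not 0 <= lumen_fraction < 1:
        raise ValueError("lumen_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    tissue = 1.0 - lumen_fraction
    p = np.array([
        tissue * surfaces.micro_pct / 100.0,
        tissue * surfaces.macro_pct / 100.0,
        tissue * (100.0 - surfaces.micro_pct - surfaces.macro_pct) / 100.0,
        lumen_fraction,
    ])
    labels = rng.choice(np.array(("micro", "macro", "non_steatotic", "lumen"),
                                 dtype=object), size=n_tiles, p=p / p.sum())
    return TileGrid(labels=labels)


def fixture_fig10() -> tuple[PKParams, ConcentrationSeries]:
    """Packaged worked example: a control codeine-6-glucuronide replicate.

    Returns the fitted curve parameters (A = 2.168, B = 5.397) and the
    noiseless series they generate on the default ten-point grid.
    """
    params = PKParams(A=2.168, B=5.397)
    t = np.asarray(DEFAULT_TIME_GRID, dtype=float)
    series = ConcentrationSeries(
        animal_id="control_00004", group="control",
        analyte="codeine_6_glucuronide", times=t,
        concentrations=evaluate_curve(t, params))
    return params, series
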