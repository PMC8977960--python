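"""Generator configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import calibration

__all__ = ["GeneratorConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid generator configuration."""


# Share of total muscle CSA and in-plane aspect (row/col half-axis ratio) of
# each compartment; shares follow typical L3 anatomy and sum to one.
DEFAULT_COMPARTMENT_GEOMETRY = {
    "psoas_L": {"fraction": 0.12, "aspect": 0.8},
    "psoas_R": {"fraction": 0.12, "aspect": 0.8},
    "quadratus_L": {"fraction": 0.08, "aspect": 0.6},
    "quadratus_R": {"fraction": 0.08, "aspect": 0.6},
    "rectus_L": {"fraction": 0.10, "aspect": 0.5},
    "rectus_R": {"fraction": 0.10, "aspect": 0.5},
    "autochthonous_L": {"fraction": 0.20, "aspect": 0.7},
    "autochthonous_R": {"fraction": 0.20, "aspect": 0.7},
}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort + PDFF slice generator.

    Defaults reproduce the study conditions: n = 335 subjects, 95/335 obese,
    stratum male fractions 136/240 and 52/95, marginals and correlation
    targets calibrated to the printed cohort tables.  ``pixel_spacing`` is
    metadata (the source protocol states a 256 x 256 matrix but no in-plane
    field of view); 1.5 mm is a typical abdominal Dixon resolution.
    """

    n_subjects: int = 335
    seed: int = 0
    obese_fraction: float = 95 / 335
    male_fraction: dict = field(
        default_factory=lambda: {"non_obese": 136 / 240, "obese": 52 / 95}
    )
    stratum_marginals: pd.DataFrame = field(
        default_factory=calibration.default_marginals
    )
    correlation_targets: list = field(
        default_factory=calibration.default_correlation_targets
    )
    risk_factor_rates: dict = field(
        default_factory=calibration.default_risk_factor_rates
    )
    grid_size: int = 160
    pixel_spacing: float = 1.5  # mm per voxel edge
    septum_fat_fraction_range: tuple = (20.5, 28.0)  # percent, strictly > 20
    compartment_geometry: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COMPARTMENT_GEOMETRY.items()
        }
    )

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not 0 < self.obese_fraction < 1:
            raise ConfigError("obese_fraction must lie strictly in (0, 1)")
        for k in ("non_obese", "obese"):
            if not 0 <= self.male_fraction.get(k, -1) <= 1:
                raise ConfigError(f"male_fraction[{k!r}] must lie in [0, 1]")
        marg = self.stratum_marginals
        required = {"variable", "obesity", "sex", "mean", "sd", "lo", "hi"}
        if not required <= set(marg.columns):
            raise ConfigError(f"stratum_marginals needs columns {sorted(required)}")
        if (marg["sd"] <= 0).any():
            bad = marg.loc[marg["sd"] <= 0, "variable"].tolist()
            raise ConfigError(f"non-positive sd for variables {bad}")
        if (marg.loc[marg["variable"] == "height", "mean"] <= 0).any():
            raise ConfigError("height marginals must be positive")
        lo, hi = self.septum_fat_fraction_range
        if not 20.0 < lo < hi <= 100.0:
            raise ConfigError(
                "septum_fat_fraction_range must lie strictly above 20 % fat"
            )
        if self.grid_size < 32:
            raise ConfigError("grid_size too small to host eight compartments")
        if not self.pixel_spacing > 0:
            raise ConfigError("pixel_spacing must be positive")
        total = sum(g["fraction"] for g in self.compartment_geometry.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError("compartment fractions must sum to 1")

    def marginal(self, variable: str, obesity: str, sex: str):
        """(mean, sd, lo, hi) for a variable in one (obesity, sex) stratum."""
        marg = self.stratum_marginals
        rows = marg[(marg["variable"] == variable) & (marg["obesity"] == obesity)]
        row = rows[rows["sex"] == sex]
        if row.empty:
            row = rows[rows["sex"] == "any"]
        if row.empty:
            raise ConfigError(f"no marginal for {variable} in stratum ({obesity}, {sex})")
        r = row.iloc[0]
        return float(r["mean"]), float(r["sd"]), float(r["lo"]), float(r["hi"])


def _to_plain(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["stratum_marginals"] = cfg.stratum_marginals.replace(
        {np.inf: ".inf", -np.inf: "-.inf"}
    ).to_dict(orient="records")
    d["septum_fat_fraction_range"] = list(cfg.septum_fat_fraction_range)
    return d


def save_config(cfg: GeneratorConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_config(path) -> GeneratorConfig:
    """Load a YAML config; missing keys fall back to calibrated defaults."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed YAML{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    kwargs = {}
    for key in (
        "n_subjects", "seed", "obese_fraction", "male_fraction",
        "correlation_targets", "risk_factor_rates", "grid_size",
        "pixel_spacing", "compartment_geometry",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "septum_fat_fraction_range" in raw:
        kwargs["septum_fat_fraction_range"] = tuple(raw["septum_fat_fraction_range"])
    if "stratum_marginals" in raw:
        df = pd.DataFrame(raw["stratum_marginals"])
        inf_map = {".inf": np.inf, "-.inf": -np.inf}
        for col in ("lo", "hi"):
            df[col] = [inf_map.get(v, v) for v in df[col]]
        df[["mean", "sd", "lo", "hi"]] = df[["mean", "sd", "lo", "hi"]].astype(float)
        kwargs["stratum_marginals"] = df
    try:
        return GeneratorConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid config field: {exc}") from exc
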