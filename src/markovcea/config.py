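"""YAML scenario schema: strict loading and validation.

A scenario file holds everything needed for one country's analysis — costs,
utilities, willingness-to-pay threshold, survival inputs and a life table.
Loading is strict: unknown keys are rejected, every validation failure names
the offending key, and missing optional keys fall back to documented
defaults.  Two fixtures covering the US and China payer perspectives ship
with the package (``markovcea.data``).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .errors import ConfigError
from .markov import ScenarioConfig
from .synthetic import LifeTable, make_life_table_fixture, read_life_table
from .weibull import WeibullParams, calibrate_scale_to_median

__all__ = ["load_config", "packaged_config_path", "REQUIRED_KEYS", "OPTIONAL_DEFAULTS"]

REQUIRED_KEYS = (
    "country",
    "wtp",
    "drug_cost_per_cycle",
    "arm_drugs",
    "imaging_cost_per_cycle",
    "bsc_cost_per_cycle",
    "ae_unit_cost",
    "ae_incidence",
    "utility_pfs",
    "utility_pd",
    "survival",
    "life_table",
)

OPTIONAL_DEFAULTS = {
    "cycle_length_days": 21.0,
    "horizon_years": 10.0,
    "start_age": 55.0,
    "discount_rate": 0.03,
    "intervention_arm": "TXT",
    "comparator_arm": "TX",
    "ranges": {},
    "psa_fixed": ["trastuzumab", "capecitabine"],
    "subgroups": {},
    "cny_per_usd": 6.9851,
}

_ALL_KEYS = set(REQUIRED_KEYS) | set(OPTIONAL_DEFAULTS)


def _parse_weibull(node, key: str) -> WeibullParams:
    if not isinstance(node, dict):
        raise ConfigError(f"{key}: expected a mapping with survival parameters")
    if "median_months" in node:
        extra = set(node) - {"median_months", "shape_gamma"}
        if extra:
            raise ConfigError(f"{key}: unknown keys {sorted(extra)}")
        return calibrate_scale_to_median(
            float(node["median_months"]), float(node.get("shape_gamma", 1.1))
        )
    if "scale_lambda" in node:
        extra = set(node) - {"scale_lambda", "shape_gamma"}
        if extra:
            raise ConfigError(f"{key}: unknown keys {sorted(extra)}")
        return WeibullParams(float(node["scale_lambda"]), float(node.get("shape_gamma", 1.1)))
    raise ConfigError(f"{key}: give either median_months or scale_lambda (plus shape_gamma)")


def _parse_survival_block(node, key: str) -> dict[str, dict[str, WeibullParams]]:
    out: dict[str, dict[str, WeibullParams]] = {}
    if not isinstance(node, dict):
        raise ConfigError(f"{key}: expected arm -> endpoint -> parameters mapping")
    for arm, endpoints in node.items():
        if not isinstance(endpoints, dict):
            raise ConfigError(f"{key}.{arm}: expected endpoint mapping")
        unknown = set(endpoints) - {"pfs", "os"}
        if unknown:
            raise ConfigError(f"{key}.{arm}: unknown endpoints {sorted(unknown)}")
        out[arm] = {
            ep: _parse_weibull(spec, f"{key}.{arm}.{ep}") for ep, spec in endpoints.items()
        }
    return out


def _parse_life_table(node, base_dir: Path) -> LifeTable:
    if not isinstance(node, dict):
        raise ConfigError("life_table: expected a mapping with 'fixture' or 'path'")
    if "fixture" in node and "path" in node:
        raise ConfigError("life_table: give either 'fixture' or 'path', not both")
    if "fixture" in node:
        fx = node["fixture"]
        try:
            return make_life_table_fixture(
                int(fx["age_start"]),
                int(fx["age_end"]),
                float(fx["q0"]),
                float(fx["doubling_years"]),
            )
        except KeyError as exc:
            raise ConfigError(f"life_table.fixture: missing key {exc.args[0]!r}")
    if "path" in node:
        p = Path(node["path"])
        if not p.is_absolute():
            p = base_dir / p
        return read_life_table(p)
    raise ConfigError("life_table: give either 'fixture' or 'path'")


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario YAML file into a :class:`ScenarioConfig`."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ConfigError(
            "empty configuration file; required keys: " + ", ".join(REQUIRED_KEYS)
        )
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _ALL_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    missing = [k for k in REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"missing required configuration keys: {missing}")

    merged = {**OPTIONAL_DEFAULTS, **raw}
    cny_rate = float(merged.pop("cny_per_usd"))
    if not cny_rate > 0:
        raise ConfigError("cny_per_usd: must be positive")

    def costs_in_usd(node, key: str) -> dict[str, float]:
        if not isinstance(node, dict):
            raise ConfigError(f"{key}: expected a name -> cost mapping")
        out = {}
        for name, v in node.items():
            try:
                out[str(name)] = float(v)
            except (TypeError, ValueError):
                raise ConfigError(f"{key}.{name}: not a number: {v!r}")
        return out

    cfg = ScenarioConfig(
        country=str(merged["country"]),
        wtp=float(merged["wtp"]),
        drug_cost=costs_in_usd(merged["drug_cost_per_cycle"], "drug_cost_per_cycle"),
        arm_drugs={a: list(d) for a, d in merged["arm_drugs"].items()},
        imaging_cost_per_cycle=float(merged["imaging_cost_per_cycle"]),
        bsc_cost_per_cycle=float(merged["bsc_cost_per_cycle"]),
        ae_unit_cost=costs_in_usd(merged["ae_unit_cost"], "ae_unit_cost"),
        ae_incidence={
            a: {str(k): float(v) for k, v in inc.items()}
            for a, inc in merged["ae_incidence"].items()
        },
        utility_pfs=float(merged["utility_pfs"]),
        utility_pd=float(merged["utility_pd"]),
        survival=_parse_survival_block(merged["survival"], "survival"),
        life_table=_parse_life_table(merged["life_table"], path.parent),
        cycle_length_days=float(merged["cycle_length_days"]),
        horizon_years=float(merged["horizon_years"]),
        start_age=float(merged["start_age"]),
        discount_rate=float(merged["discount_rate"]),
        intervention_arm=str(merged["intervention_arm"]),
        comparator_arm=str(merged["comparator_arm"]),
        ranges={
            str(k): (float(v[0]), float(v[1])) for k, v in dict(merged["ranges"]).items()
        },
        psa_fixed=tuple(merged["psa_fixed"]),
        subgroups={
            str(name): _parse_survival_block(node["survival"], f"subgroups.{name}.survival")
            for name, node in dict(merged["subgroups"]).items()
        },
    )
    for arm, inc in cfg.ae_incidence.items():
        for k, v in inc.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"ae_incidence.{arm}.{k}: must be in [0, 1], got {v}")
    return cfg.validate()


def packaged_config_path(name: str) -> Path:
    """Path to a packaged scenario fixture, e.g. 'usa_base' or 'china_base'."""
    ref = importlib.resources.files("markovcea").joinpath(f"data/{name}.yaml")
    p = Path(str(ref))
    if not p.exists():
        raise ConfigError(f"no packaged configuration named {name!r}")
    return p
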