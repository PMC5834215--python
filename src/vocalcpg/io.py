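"""Configuration, call-record I/O and pipeline orchestration.

A single :class:`RunConfig` (YAML/JSON) carries every stage's settings and
one global seed; the seed is expanded into independent per-stage streams
so that re-running any one stage cannot perturb another.  Every result
bundle records provenance: the config hash, the seed, and the package
version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cpg import CPGParams, OscillatorParams
from .development import fit_day_map
from .regimes import (
    DEFAULT_GAMMA1_GRID,
    DEFAULT_I_GRID,
    RegimeThresholds,
    proportions_from_diagram,
    sweep_regime_diagram,
)
from .stats import (
    REQUIRED_COLUMNS,
    condition_proportions,
    call_rate_test,
    fit_duration_model,
    fit_occurrence_glm,
    group_syllables,
)
from .synth import DevGenConfig, HelioxGenConfig, gen_development_calls, gen_heliox_sessions

__all__ = [
    "SchemaError",
    "RunConfig",
    "load_call_records",
    "write_call_records",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A call-record table violates the declared schema; rows are named."""


def load_call_records(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a call-record CSV.

    Required columns: subject, day, session, condition, call_type,
    onset_s, offset_s (``order`` optional).  ``column_map`` renames
    source columns to the schema (for importing externally formatted
    tables).  Violations are reported with 0-based data row numbers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df["day"] = pd.to_numeric(df["day"], errors="coerce")
    df["onset_s"] = pd.to_numeric(df["onset_s"], errors="coerce")
    df["offset_s"] = pd.to_numeric(df["offset_s"], errors="coerce")
    problems = []
    bad_num = df.index[df[["day", "onset_s", "offset_s"]].isna().any(axis=1)]
    problems += [(int(i), "non-numeric day/onset/offset") for i in bad_num]
    ok = df.drop(index=bad_num)
    problems += [(int(i), "offset_s <= onset_s") for i in ok.index[ok["offset_s"] <= ok["onset_s"]]]
    problems += [(int(i), "day < 1") for i in ok.index[ok["day"] < 1]]
    bad_cond = ok.index[~ok["condition"].isin(["air", "heliox"])]
    problems += [(int(i), "condition not in {air, heliox}") for i in bad_cond]
    if problems:
        listing = "; ".join(f"row {i}: {msg}" for i, msg in sorted(problems)[:20])
        raise SchemaError(f"{len(problems)} invalid rows: {listing}")
    df["day"] = df["day"].astype(int)
    return df


def write_call_records(df: pd.DataFrame, path) -> None:
    cols = [c for c in (*REQUIRED_COLUMNS, "order") if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def _seed_for(seed: int, stage: str) -> int:
    """Stable per-stage substream seed derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Top-level run settings; see module docstring.

    ``pipeline`` selects the orchestration: ``model`` (regime sweep ->
    proportions -> day map against observed/synthetic development data)
    or ``heliox`` (synthetic or loaded records -> grouping -> GLMs).
    """

    pipeline: str = "model"
    seed: int = 0
    out_dir: str = "results"
    gamma1: float = 2.5
    gamma2: float = 25.0
    alpha21: float = 4.0
    alpha12: float = 0.015
    a1_range: tuple = (-0.1, 0.1)
    a2_range: tuple = (-1.0, 1.0)
    p0: float = 0.1
    k0: float = 32.0
    x20: float = 5.0
    dt: float = 0.01
    n_burn: int = 500
    n_keep: int = 2000
    gamma1_grid: list = field(default_factory=lambda: DEFAULT_GAMMA1_GRID.tolist())
    I_grid: list = field(default_factory=lambda: DEFAULT_I_GRID.tolist())
    thresholds: dict = field(default_factory=dict)
    records_csv: str | None = None
    dev_gen: dict = field(default_factory=dict)
    heliox_gen: dict = field(default_factory=dict)

    def __post_init__(self):
        self.a1_range = tuple(self.a1_range)
        self.a2_range = tuple(self.a2_range)
        self.gamma1_grid = [float(g) for g in self.gamma1_grid]
        self.I_grid = [float(i) for i in self.I_grid]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        data = asdict(self)
        data["a1_range"] = list(data["a1_range"])
        data["a2_range"] = list(data["a2_range"])
        return yaml.safe_dump(data, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        data = asdict(self)
        data.pop("out_dir")
        data["a1_range"] = list(data["a1_range"])
        data["a2_range"] = list(data["a2_range"])
        return hashlib.sha256(yaml.safe_dump(data, sort_keys=True).encode()).hexdigest()[:16]

    def cpg_params(self, gamma1: float | None = None) -> CPGParams:
        return CPGParams(
            resp=OscillatorParams(
                gamma=gamma1 if gamma1 is not None else self.gamma1,
                a_min=self.a1_range[0], a_max=self.a1_range[1],
                coupling_in=self.alpha21,
            ),
            lar=OscillatorParams(
                gamma=self.gamma2,
                a_min=self.a2_range[0], a_max=self.a2_range[1],
                coupling_in=self.alpha12,
            ),
            p0=self.p0, k0=self.k0, x20=self.x20,
        )


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _model_pipeline(config: RunConfig, out: Path) -> dict:
    params = config.cpg_params()
    thresholds = RegimeThresholds(**config.thresholds) if config.thresholds else None
    diagram = sweep_regime_diagram(
        np.asarray(config.gamma1_grid), np.asarray(config.I_grid), params,
        thresholds, dt=config.dt, n_burn=config.n_burn, n_keep=config.n_keep,
    )
    curve = proportions_from_diagram(diagram)
    diagram.to_csv(out / "regime_diagram.csv")
    curve.to_csv(out / "proportion_curves.csv")

    if config.records_csv:
        records = load_call_records(config.records_csv)
    else:
        dev_cfg = DevGenConfig(**{"seed": _seed_for(config.seed, "dev"), **config.dev_gen})
        records = gen_development_calls(dev_cfg)
        write_call_records(records, out / "development_records.csv")
    calls = group_syllables(records)
    counts = (
        calls.groupby(["day", "call_type"]).size().rename("n").reset_index()
    )
    totals = counts.groupby("day")["n"].transform("sum")
    obs = counts.assign(proportion=counts["n"] / totals)[["day", "call_type", "proportion"]]
    obs.to_csv(out / "observed_proportions.csv", index=False)

    day_map = fit_day_map(curve, obs)
    result = {"day_map": day_map.to_dict(), "provenance": _provenance(config)}
    (out / "day_map.json").write_text(json.dumps(result, indent=2))
    return result


def _heliox_pipeline(config: RunConfig, out: Path) -> dict:
    if config.records_csv:
        records = load_call_records(config.records_csv)
    else:
        hx_cfg = HelioxGenConfig(**{"seed": _seed_for(config.seed, "heliox"), **config.heliox_gen})
        records = gen_heliox_sessions(hx_cfg)
        write_call_records(records, out / "heliox_records.csv")
    calls = group_syllables(records)
    props = condition_proportions(calls)
    props.to_csv(out / "condition_proportions.csv", index=False)

    mean_props = props.groupby(["condition", "call_type"])["proportion"].mean()

    def pct_increase(ct):
        air = mean_props.get(("air", ct), np.nan)
        hel = mean_props.get(("heliox", ct), np.nan)
        return float((hel - air) / air * 100.0) if air and np.isfinite(air) else float("nan")

    glms = {}
    for ct in ("trill", "twitter"):
        g = fit_occurrence_glm(calls, ct)
        glms[ct] = {
            "beta3": g.beta3,
            "beta3_se": g.beta3_se,
            "p": float(g.pvalues["heliox"]),
            "effect_size_r": g.effect_size_r,
            "pct_increase_raw": pct_increase(ct),
            "separation": g.separation,
        }
    contact = records[records["call_type"] == "contact"]
    dur = fit_duration_model(contact)
    session_rates = (
        calls.groupby(["subject", "session", "condition"]).size().rename("n").reset_index()
    )
    piv = session_rates.pivot_table(
        index=["subject", "session"], columns="condition", values="n"
    ).dropna()
    stat, p_rate = call_rate_test(piv["air"].to_numpy(), piv["heliox"].to_numpy())

    result = {
        "occurrence": glms,
        "duration": {
            "beta3": dur.beta3,
            "beta3_se": dur.beta3_se,
            "p": float(dur.pvalues["heliox"]),
            "cohens_f2": dur.cohens_f2,
            "power": dur.power,
            "pct_change": dur.beta3 * 100.0,
        },
        "call_rate": {"wilcoxon_stat": stat, "p": p_rate},
        "provenance": _provenance(config),
    }
    (out / "heliox_stats.json").write_text(json.dumps(result, indent=2))
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns the result bundle.

    Stage failures propagate as exceptions prefixed with the stage name.
    Outputs land in ``config.out_dir``; numeric outputs are byte-identical
    across runs with the same (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {"model": _model_pipeline, "heliox": _heliox_pipeline}
    if config.pipeline not in stages:
        raise ValueError(f"unknown pipeline {config.pipeline!r}; choose from {sorted(stages)}")
    try:
        return stages[config.pipeline](config, out)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {config.pipeline!r} failed: {e}") from e
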