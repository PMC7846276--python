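"""Trial-table and configuration I/O.

Trial tables travel as comma-separated UTF-8 CSV with a required header and
empty fields for missing values, in the fixed column order of
``TRIAL_COLUMNS``.  Choice coding is global: 1 = rightward = high-rate port
under the standard contingency.  Run configurations are JSON (YAML accepted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import TaskConfig
from .synthetic import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "RunConfig", "load_config",
           "write_fit_json", "TrialParseError"]

_CONDITIONS = {"visual", "auditory", "multisensory", "neutral",
               "surebet_left", "surebet_right"}
_MANIPULATIONS = {"none", "reward_up_right", "reward_down_right",
                  "prob_reward_left_on_high", "inactivation_left",
                  "inactivation_right", "saline"}


class TrialParseError(ValueError):
    """Malformed trial table; message lists offending rows/columns."""


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def _reject(problems: list[str], mask: np.ndarray, message: str) -> None:
    if mask.any():
        rows = np.flatnonzero(mask)[:10] + 2  # header is line 1
        problems.append(f"{message} (lines {', '.join(map(str, rows))}"
                        + (", ..." if mask.sum() > 10 else "") + ")")


def read_trials(path, rate_min: float = 9.0, rate_max: float = 16.0,
                strict: bool = True) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Rows violating the schema invariants raise :class:`TrialParseError`
    listing the offending lines (or are dropped with ``strict=False``).
    Missing lagged history columns are reconstructed from within-session
    ordering, with the first trial of each session left missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in TRIAL_COLUMNS if c not in df.columns
                    and c not in ("prev_choice", "prev_rewarded")]
    if missing_cols:
        raise TrialParseError(f"missing required columns: {missing_cols}")

    problems: list[str] = []
    cond = df["condition"].astype(str)
    _reject(problems, ~cond.isin(_CONDITIONS).to_numpy(), "unknown condition label")
    choice = pd.to_numeric(df["choice"], errors="coerce")
    bad_choice = (~choice.isin([0.0, 1.0]) & choice.notna()).to_numpy()
    _reject(problems, bad_choice, "choice must be 0, 1 or empty")
    _reject(problems, ~df["manipulation"].astype(str).isin(_MANIPULATIONS).to_numpy(),
            "unknown manipulation label")
    _reject(problems, ~df["contingency"].astype(str).isin({"standard", "reversed"}).to_numpy(),
            "contingency must be standard or reversed")

    is_surebet = cond.str.startswith("surebet").to_numpy()
    rate = pd.to_numeric(df["rate_nominal"], errors="coerce")
    _reject(problems, (~is_surebet & ~rate.between(rate_min, rate_max)).to_numpy(),
            f"rate_nominal must lie in [{rate_min:g}, {rate_max:g}] on discrimination trials")
    _reject(problems, (is_surebet & rate.notna().to_numpy()),
            "rate_nominal must be empty on sure-bet trials")

    if problems:
        if strict:
            raise TrialParseError("; ".join(problems))
        keep = cond.isin(_CONDITIONS).to_numpy() & ~bad_choice
        df = df[keep].reset_index(drop=True)

    df["choice"] = choice
    df["rate_nominal"] = rate

    # reconstruct lagged columns when absent or empty
    for col, src in (("prev_choice", "choice"), ("prev_rewarded", "rewarded")):
        if col not in df.columns or df[col].isna().all():
            df[col] = df.groupby("session_id", sort=False)[src].shift(1)
    return df[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs: the task, what to simulate, which
    model specs to fit, and output/bootstrap settings."""

    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0
    trials_path: str | None = None    # load instead of simulating
    simulate: dict | None = None      # {"n_trials":..., "n_rats":..., ...}
    fit_specs: list[dict] = field(default_factory=lambda: [
        {"family": "psychometric", "lapse_variant": "variable"},
        {"family": "exploration"},
    ])
    manipulation: dict | None = None  # {"kind":..., "side":..., "factor":...}
    deficit: dict | None = None       # {"type":..., "K":..., "side":...}
    n_boot: int = 1000
    ci_method: str = "hessian"
    out_dir: str = "lapsekit_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        task = d.pop("task", {})
        cfg = cls(task=TaskConfig(**task) if isinstance(task, dict) else task)
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        if not isinstance(cfg.seed, int):
            raise ValueError("seed must be an integer")
        return cfg


def load_config(path) -> RunConfig:
    """Load a RunConfig from JSON or YAML."""
    text = Path(path).read_text()
    return RunConfig.from_dict(yaml.safe_load(text) or {})


def write_fit_json(fit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True))
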