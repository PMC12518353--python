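"""CSV/JSON schemas and run configuration.

Canonical trial layout is wide — one row per trial with the five allocation
counts as columns and the draws packed into a single ``bin:value`` delimited
column (normalized values, 17 significant digits so round trips are exact to
float precision).  A long-layout importer (one row per draw plus an estimate
row per trial) is provided for externally produced data.  Every artifact
written by the pipeline embeds the master seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import TrialRecord
from .biasstats import BiasSummary, ExclusionReport, ProportionTest
from .stimuli import DEFAULT_N_BINS

__all__ = [
    "RunConfig",
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "read_trials_long",
    "summaries_to_frame",
    "proportion_tests_to_frame",
    "write_json_report",
]

_WIDE_COLUMNS = (
    ["participant_id", "trial_index", "condition", "budget", "multiplier"]
    + [f"count_{k}" for k in range(1, DEFAULT_N_BINS + 1)]
    + ["draws", "estimate_raw"]
)


class TrialValidationError(ValueError):
    """Raised when a trials file violates the schema or a record invariant."""


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for CLI runs; all sub-seeds derive from ``seed``."""

    seed: int = 0
    n_participants: int = 145
    budget_split: float = 0.5
    trials_per_condition: int = 4
    mu_w: float = 0.51
    sigma_w: float = 0.22
    kappa: float = 0.5
    sigma_e: float = 0.05
    n_boot: int = 2000
    n_chains: int = 4
    n_iterations: int = 2000
    n_warmup: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise TrialValidationError(f"config file {path} must be a flat mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise TrialValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def hash(self) -> str:
        canon = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _format_draws(record: TrialRecord) -> str:
    return ";".join(
        f"{int(k)}:{v:.17g}" for k, v in zip(record.draw_bins, record.draw_values)
    )


def _parse_draws(cell: str) -> tuple[np.ndarray, np.ndarray]:
    if not cell:
        return np.empty(0, dtype=int), np.empty(0)
    bins, values = [], []
    for token in cell.split(";"):
        k, _, v = token.partition(":")
        bins.append(int(k))
        values.append(float(v))
    return np.array(bins, dtype=int), np.array(values)


def write_trials(
    records,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write trial records as wide CSV; optional provenance comment header."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "trial_index": r.trial_index,
            "condition": r.condition,
            "budget": r.budget,
            "multiplier": f"{r.multiplier:.17g}",
            "draws": _format_draws(r),
            "estimate_raw": f"{r.estimate_raw:.17g}",
        }
        for k in range(1, DEFAULT_N_BINS + 1):
            row[f"count_{k}"] = int(r.counts[k - 1])
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_WIDE_COLUMNS)
    path = Path(path)
    with path.open("w") as fh:
        if seed is not None or config_hash is not None:
            fh.write(f"# skewsample seed={seed} config_hash={config_hash}\n")
        frame.to_csv(fh, index=False)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read wide-layout trials CSV, validating every record invariant.

    Violations are rejected with the offending (1-based) data row number.
    """
    frame = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    if frame.empty and frame.columns.size == 0:
        raise TrialValidationError(f"{path}: empty file without header")
    missing = set(_WIDE_COLUMNS) - set(frame.columns)
    if missing:
        raise TrialValidationError(f"{path}: missing columns {sorted(missing)}")
    records: list[TrialRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        counts = np.array(
            [int(getattr(row, f"count_{k}")) for k in range(1, DEFAULT_N_BINS + 1)]
        )
        draw_bins, draw_values = _parse_draws(
            "" if pd.isna(row.draws) else str(row.draws)
        )
        record = TrialRecord(
            participant_id=str(row.participant_id),
            condition=str(row.condition),
            budget=int(row.budget),
            counts=counts,
            draw_bins=draw_bins,
            draw_values=draw_values,
            multiplier=float(row.multiplier),
            estimate_raw=float(row.estimate_raw),
            trial_index=int(row.trial_index),
        )
        try:
            record.validate()
        except ValueError as exc:
            raise TrialValidationError(f"{path}: row {i}: {exc}") from exc
        records.append(record)
    return records


def read_trials_long(path: str | Path) -> list[TrialRecord]:
    """Import long-layout trials: one row per draw plus one estimate row per trial.

    Required columns: participant_id, trial_index, condition, budget,
    multiplier, row_type ('draw' or 'estimate'), bin (draw rows), value
    (normalized draw value, or the raw estimate on estimate rows).
    """
    frame = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    required = {
        "participant_id",
        "trial_index",
        "condition",
        "budget",
        "multiplier",
        "row_type",
        "bin",
        "value",
    }
    missing = required - set(frame.columns)
    if missing:
        raise TrialValidationError(f"{path}: missing columns {sorted(missing)}")
    records: list[TrialRecord] = []
    grouped = frame.groupby(["participant_id", "trial_index"], sort=False)
    for (pid, tidx), grp in grouped:
        draws = grp[grp["row_type"] == "draw"]
        est = grp[grp["row_type"] == "estimate"]
        if len(est) != 1:
            raise TrialValidationError(
                f"{path}: trial ({pid}, {tidx}) needs exactly one estimate row"
            )
        draw_bins = draws["bin"].to_numpy(dtype=int)
        counts = np.bincount(draw_bins, minlength=DEFAULT_N_BINS + 1)[1:]
        record = TrialRecord(
            participant_id=str(pid),
            condition=str(grp["condition"].iloc[0]),
            budget=int(grp["budget"].iloc[0]),
            counts=counts,
            draw_bins=draw_bins,
            draw_values=draws["value"].to_numpy(dtype=float),
            multiplier=float(grp["multiplier"].iloc[0]),
            estimate_raw=float(est["value"].iloc[0]),
            trial_index=int(tidx),
        )
        try:
            record.validate()
        except ValueError as exc:
            raise TrialValidationError(f"{path}: trial ({pid}, {tidx}): {exc}") from exc
        records.append(record)
    return records


_SUMMARY_COLUMNS = [
    "condition",
    "budget",
    "mean_sampling_bias",
    "sampling_bias_ci_low",
    "sampling_bias_ci_high",
    "mean_estimation_deviation",
    "estimation_deviation_ci_low",
    "estimation_deviation_ci_high",
    "mean_estimation_adjustment",
    "estimation_adjustment_ci_low",
    "estimation_adjustment_ci_high",
    "n_trials",
]

_PROPORTION_COLUMNS = [
    "condition",
    "bin_index",
    "successes",
    "total",
    "p0",
    "proportion",
    "p_value",
    "ci_low",
    "ci_high",
]


def summaries_to_frame(summaries: list[BiasSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "condition": s.condition,
                "budget": s.budget,
                "mean_sampling_bias": s.mean_sampling_bias,
                "sampling_bias_ci_low": s.ci_sampling_bias[0],
                "sampling_bias_ci_high": s.ci_sampling_bias[1],
                "mean_estimation_deviation": s.mean_estimation_deviation,
                "estimation_deviation_ci_low": s.ci_estimation_deviation[0],
                "estimation_deviation_ci_high": s.ci_estimation_deviation[1],
                "mean_estimation_adjustment": s.mean_estimation_adjustment,
                "estimation_adjustment_ci_low": s.ci_estimation_adjustment[0],
                "estimation_adjustment_ci_high": s.ci_estimation_adjustment[1],
                "n_trials": s.n_trials,
            }
        )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def proportion_tests_to_frame(tests: list[tuple[str, ProportionTest]]) -> pd.DataFrame:
    rows = []
    for condition, t in tests:
        rows.append(
            {
                "condition": condition,
                "bin_index": t.bin_index,
                "successes": t.successes,
                "total": t.total,
                "p0": t.p0,
                "proportion": t.proportion,
                "p_value": t.p_value,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
            }
        )
    return pd.DataFrame(rows, columns=_PROPORTION_COLUMNS)


def write_json_report(payload: dict, path: str | Path, seed: int, config_hash: str) -> None:
    """Write a JSON artifact with provenance metadata embedded."""
    doc = {"_meta": {"seed": seed, "config_hash": config_hash}}
    doc.update(payload)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, ExclusionReport):
            return asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(doc, indent=2, default=default) + "\n")
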