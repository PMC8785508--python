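"""File I/O: profile CSV, CMDQ CSV, weight/threshold configs, results.

CSV dialect is fixed: comma-separated, UTF-8, ``.`` decimal point,
locale-independent.  Profile files carry one row per worker with the 16
raw rubric columns (and an optional ``worker_id``); configs are JSON or
YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .cmdq import CmdqItem
from .core import (
    ExposureProfile,
    RiskThresholds,
    ValidationError,
    WeightSet,
    classify_risk,
    derive_weights,
    moreba_score,
)

__all__ = [
    "PROFILE_COLUMNS",
    "read_profiles",
    "write_profiles",
    "read_cmdq_responses",
    "load_weights",
    "load_thresholds",
    "score_profiles",
]

#: The 16 raw rubric columns of a profile CSV, in canonical order.
PROFILE_COLUMNS: tuple[str, ...] = tuple(
    f.name for f in fields(ExposureProfile)
)


def read_profiles(path: str | Path) -> list[ExposureProfile]:
    """Read and validate worker exposure profiles from CSV.

    Every rubric column must be present; errors cite the offending row
    (1-based, excluding the header) and column.
    """
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    profiles = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        kwargs = {}
        for col in PROFILE_COLUMNS:
            raw = getattr(row, col)
            try:
                val = int(raw)
                if val != float(raw):
                    raise ValueError
            except (ValueError, TypeError):
                raise ValidationError(
                    f"{path}: row {i}, column {col!r}: {raw!r} is not an integer"
                ) from None
            kwargs[col] = val
        try:
            profiles.append(ExposureProfile(**kwargs))
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i}: {err}") from None
    return profiles


def write_profiles(
    profiles: Sequence[ExposureProfile],
    path: str | Path,
    outcomes: Sequence[float] | None = None,
) -> None:
    """Write profiles (optionally with a questionnaire outcome column)."""
    df = pd.DataFrame([asdict(p) for p in profiles], columns=list(PROFILE_COLUMNS))
    if outcomes is not None:
        if len(outcomes) != len(profiles):
            raise ValidationError("outcomes length must match profiles")
        df["cmdq_total"] = list(outcomes)
    df.to_csv(path, index=False)


def read_cmdq_responses(path: str | Path) -> dict[str, list[CmdqItem]]:
    """Read per-worker-region questionnaire responses from CSV.

    Expected columns: worker_id, region, frequency, severity,
    interference (category labels, matched case-insensitively).
    """
    df = pd.read_csv(path)
    needed = ["worker_id", "region", "frequency", "severity", "interference"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    by_worker: dict[str, list[CmdqItem]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            item = CmdqItem(
                region=str(row.region),
                frequency=row.frequency,
                severity=row.severity,
                interference=row.interference,
            )
            item.score  # force category validation now, with row context
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i}: {err}") from None
        by_worker.setdefault(str(row.worker_id), []).append(item)
    return by_worker


def _load_config(path: str | Path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def load_weights(path: str | Path | None = None) -> WeightSet:
    """Load a coefficient set from a JSON/YAML config (default: packaged).

    A config either gives ``direct_effects`` (+ ``strain_coefficient``),
    from which the score-equation weights are derived, or hand-set
    ``indirect_effects`` used as-is.
    """
    if path is None:
        return derive_weights()
    cfg = _load_config(path)
    if "indirect_effects" in cfg:
        return WeightSet(
            strain_coefficient=float(cfg.get("strain_coefficient", 0.0) or 1.0),
            direct_effects=cfg.get("direct_effects", {}) or dict(cfg["indirect_effects"]),
            indirect_effects=dict(cfg["indirect_effects"]),
        )
    return derive_weights(
        cfg["direct_effects"], float(cfg.get("strain_coefficient", 0.783))
    )


def load_thresholds(path: str | Path | None = None) -> RiskThresholds:
    """Load risk cutoffs from config (default: published cutoffs)."""
    if path is None:
        return RiskThresholds()
    cfg = _load_config(path)
    if "thresholds" in cfg:
        cfg = cfg["thresholds"]
    return RiskThresholds(
        low_moderate=float(cfg["low_moderate"]),
        moderate_high=float(cfg["moderate_high"]),
        high_very_high=float(cfg["high_very_high"]),
    )


def score_profiles(
    profiles: Iterable[ExposureProfile],
    weights: WeightSet | None = None,
    thresholds: RiskThresholds | None = None,
) -> pd.DataFrame:
    """Score profiles into a results table.

    Columns: worker (0-based), load and force sub-scores, the weighted
    score (3 decimals, the reporting precision of the coefficients), and
    the risk level.
    """
    if weights is None:
        weights = derive_weights()
    if thresholds is None:
        thresholds = RiskThresholds()
    rows = []
    for i, p in enumerate(profiles):
        s = moreba_score(p, weights)
        rows.append(
            {
                "worker": i,
                "load_subscore": p.load,
                "force_subscore": p.force,
                "moreba_score": round(s, 3),
                "risk_level": str(classify_risk(s, thresholds)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["worker", "load_subscore", "force_subscore", "moreba_score", "risk_level"],
    )


def provenance_header(seed: int | None, config: dict | None = None) -> str:
    """Comment header embedding tool version, config hash and seed."""
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# moreba {__version__} | config {cfg_hash} | seed {seed}\n"
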