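"""CSV readers and writers for trial tables and analysis outputs.

All artifacts are plain CSV; feature-space metadata (period, minimum
separation, and optionally the placement geometry) travels in a small YAML
sidecar rather than per-row.  Angles at rest are always on the raw feature
scale.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circular import CircularSpace, wrap_angle
from .data import TrialSet, trial_columns
from .exceptions import SchemaError
from .mixture import MixtureFit

logger = logging.getLogger(__name__)


def write_space_config(space: CircularSpace, path, placement_radius=None, min_center_distance=None) -> None:
    cfg = {"period": float(space.period), "min_separation": float(space.min_separation)}
    if placement_radius is not None:
        cfg["placement_radius"] = float(placement_radius)
    if min_center_distance is not None:
        cfg["min_center_distance"] = float(min_center_distance)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_space_config(path) -> tuple[CircularSpace, dict]:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "period" not in cfg or "min_separation" not in cfg:
        raise SchemaError(f"space config {path} must define period and min_separation")
    space = CircularSpace(float(cfg["period"]), float(cfg["min_separation"]))
    extras = {k: cfg[k] for k in ("placement_radius", "min_center_distance") if k in cfg}
    return space, extras


def write_trials(trials: TrialSet, path, config_path=None) -> None:
    """Write a trial table as CSV (and optionally its sidecar config)."""
    cols = trial_columns(trials.n_items)
    trials.table[cols].to_csv(path, index=False)
    if config_path is not None:
        write_space_config(trials.space, config_path)


def read_trials(
    path,
    space: CircularSpace | None = None,
    config_path=None,
    placement_radius=None,
    min_center_distance=None,
) -> TrialSet:
    """Read and validate a trial table.

    The feature space comes either from ``space`` directly or from the YAML
    sidecar at ``config_path``.  Angles are period-reduced on load.  Rows
    violating the structural invariants raise a
    :class:`~swapmix.exceptions.ValidationError` naming the offending trials;
    a missing column raises :class:`~swapmix.exceptions.SchemaError`.
    """
    if space is None:
        if config_path is None:
            raise SchemaError("read_trials needs a CircularSpace or a sidecar config path")
        space, extras = read_space_config(config_path)
        placement_radius = placement_radius or extras.get("placement_radius")
        min_center_distance = min_center_distance or extras.get("min_center_distance")

    table = pd.read_csv(path)
    n_items = sum(1 for c in table.columns if str(c).startswith("feature_"))
    if n_items == 0:
        raise SchemaError(f"{path}: no feature_* columns found")
    missing = [c for c in trial_columns(n_items) if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(table) == 0:
        warnings.warn(f"{path}: empty trial table", stacklevel=2)
        return TrialSet(space, table)

    def _indexed(col: str, prefix: str) -> bool:
        return col.startswith(prefix) and col[len(prefix) :].isdigit()

    for col in table.columns:
        if _indexed(col, "feature_") or col == "response":
            table[col] = wrap_angle(table[col].to_numpy(dtype=float), space.period)
        elif _indexed(col, "location_"):
            table[col] = wrap_angle(table[col].to_numpy(dtype=float), 360.0)
    trials = TrialSet(space, table)
    trials.validate(placement_radius=placement_radius, min_center_distance=min_center_distance)
    counts = table.groupby(["participant", "location_condition", "isi_condition"]).size()
    logger.info("read %d trials from %s:\n%s", len(table), path, counts.to_string())
    return trials


def fits_to_frame(fits: dict[tuple, MixtureFit]) -> pd.DataFrame:
    """Tabulate {(participant, location, isi): MixtureFit} as tidy rows."""
    rows = []
    for (participant, loc, isi), fit in sorted(fits.items()):
        rows.append(
            {
                "participant": participant,
                "location_condition": loc,
                "isi_condition": isi,
                "p_t": fit.params.p_t,
                "p_nt": fit.params.p_nt,
                "p_u": fit.params.p_u,
                "kappa": fit.params.kappa,
                "log_likelihood": fit.log_likelihood,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def frame_to_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
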