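"""End-to-end analysis pipeline and design-level simulation.

``run_pipeline`` reproduces the analysis order of a sequential cued-recall
study on a trial table (read from CSV or freshly simulated): per-slice
mixture fits, target and shuffle-corrected non-target histograms, heuristic
proportions, temporal/spatial swap gradients with their shuffled chance
level, and the swap-interaction Bayes factor.  Every stage writes CSV and a
JSON manifest records the seed, a config hash, and stage counts, so a run
can be reproduced exactly.

``simulate_stopping_experiment`` emulates the sequential design itself:
participants are generated and fitted one at a time and the Bayes-factor
stopping rule is applied to the accumulating Δp_NT values, exactly as an
experiment with optional stopping would unfold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import (
    DEFAULT_PRIOR_SCALE,
    StoppingTrace,
    delta_pnt,
    delta_pnt_table,
    one_sample_bf,
    paired_bf,
)
from .data import TrialSet
from .exceptions import InvalidArgumentError
from .distance import chance_mad_line, distance_profiles_table
from .histograms import (
    corrected_nontarget_histogram,
    heuristic_table,
    mean_abs_error_by_position,
    target_error_histogram,
)
from .io import fits_to_frame, frame_to_csv, read_trials, write_trials
from .mixture import fit_all_slices, fit_mixture
from .simulate import GeneratorConfig, generate_dataset, generate_participant

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to analyse and where to put the results.

    Exactly one of ``input_csv`` (with its sidecar ``space_config``) or
    ``generator`` should be provided; with neither, a default generator at
    ``seed`` is used.
    """

    outdir: Path = Path("swapmix_out")
    seed: int = 0
    input_csv: Path | None = None
    space_config: Path | None = None
    generator: GeneratorConfig | None = None
    bin_width: float | None = None  # default: period / 12
    heuristic_window: float | None = None  # default: period / 12


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all analysis stages; returns a dict of result frames and paths.

    Stages run in order and write their outputs immediately, so a failure in
    a later stage leaves earlier results on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if cfg.input_csv is not None:
        trials = read_trials(cfg.input_csv, config_path=cfg.space_config)
    else:
        gen = cfg.generator or GeneratorConfig(seed=cfg.seed)
        trials = generate_dataset(gen)
        write_trials(trials, outdir / "trials.csv", outdir / "space.yaml")
    counts["trials"] = trials.n_trials
    space = trials.space
    bin_width = cfg.bin_width or space.period / 12
    window = cfg.heuristic_window or space.period / 12

    fits = fit_all_slices(trials)
    fit_frame = fits_to_frame(fits)
    frame_to_csv(fit_frame, outdir / "fits.csv")
    counts["fits"] = len(fit_frame)

    hist_frames = []
    for (loc, isi) in trials.conditions():
        sub = trials.select(location=loc, isi=isi)
        th = target_error_histogram(sub, bin_width).to_frame()
        th["histogram"] = "target"
        nh = corrected_nontarget_histogram(sub, bin_width).to_frame()
        nh["histogram"] = "nontarget"
        for df in (th, nh):
            df["location_condition"] = loc
            df["isi_condition"] = isi
            hist_frames.append(df)
    histograms = pd.concat(hist_frames, ignore_index=True)
    frame_to_csv(histograms, outdir / "histograms.csv")

    heuristics = heuristic_table(trials, window)
    frame_to_csv(heuristics, outdir / "heuristics.csv")

    mae = mean_abs_error_by_position(trials)
    frame_to_csv(mae, outdir / "mae_by_position.csv")

    profiles = distance_profiles_table(trials)
    frame_to_csv(profiles, outdir / "distance_profiles.csv")
    chance = chance_mad_line(trials)

    params = {key: fit.params for key, fit in fits.items()}
    deltas = delta_pnt_table(params)
    bf_rows = []
    if len(deltas) >= 2:
        bf_delta = one_sample_bf(list(deltas.values())).bf10
        bf_rows.append({"test": "delta_pnt_vs_zero", "bf10": bf_delta, "n": len(deltas)})
        for isi in ("short", "long"):
            same = fit_frame.query("location_condition == 'same' and isi_condition == @isi")
            diff = fit_frame.query("location_condition == 'different' and isi_condition == @isi")
            if len(same) >= 2 and len(same) == len(diff):
                merged = same.merge(
                    diff, on="participant", suffixes=("_same", "_diff")
                )
                bf = paired_bf(merged["p_nt_same"], merged["p_nt_diff"]).bf10
                bf_rows.append(
                    {"test": f"p_nt_same_vs_different_{isi}", "bf10": bf, "n": len(merged)}
                )
    bf_frame = pd.DataFrame(bf_rows)
    frame_to_csv(bf_frame, outdir / "bayes_factors.csv")
    counts["delta_pnt_participants"] = len(deltas)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "chance_mad": chance,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", counts)
    return {
        "trials": trials,
        "fits": fit_frame,
        "histograms": histograms,
        "heuristics": heuristics,
        "mae_by_position": mae,
        "distance_profiles": profiles,
        "chance_mad": chance,
        "deltas": deltas,
        "bayes_factors": bf_frame,
        "manifest": manifest,
        "outdir": outdir,
    }


def fit_participant_conditions(config: GeneratorConfig, participant_index: int) -> dict:
    """Generate one synthetic participant and fit each condition's mixture."""
    frame = generate_participant(config, participant_index)
    trials = TrialSet(config.space, frame)
    out = {}
    for (loc, isi) in config.conditions:
        sub = trials.select(location=loc, isi=isi)
        out[(loc, isi)] = fit_mixture(sub).params
    return out


def simulate_stopping_experiment(
    config: GeneratorConfig,
    threshold: float = 10.0,
    n_max: int = 20,
    n_min: int = 2,
    r: float = DEFAULT_PRIOR_SCALE,
) -> tuple[StoppingTrace, list[float]]:
    """Run the sequential design once: recruit, fit, and test until stopping.

    Participants are generated lazily; once the Bayes factor crosses the
    threshold no further participants are simulated.  Returns the stopping
    trace and the Δp_NT values actually collected.
    """
    deltas: list[float] = []
    ns: list[int] = []
    bfs: list[float] = []
    decision, n_final = "max-n", n_max
    for p in range(n_max):
        fits = fit_participant_conditions(config, p)
        deltas.append(delta_pnt(fits))
        if len(deltas) < n_min:
            continue
        try:
            bf = one_sample_bf(deltas, r).bf10
        except InvalidArgumentError:
            bf = np.nan
        ns.append(len(deltas))
        bfs.append(bf)
        if np.isfinite(bf):
            if bf > threshold:
                decision, n_final = "H1", len(deltas)
                break
            if 1.0 / bf > threshold:
                decision, n_final = "H0", len(deltas)
                break
    return StoppingTrace(np.asarray(ns), np.asarray(bfs), decision, min(n_final, len(deltas))), deltas
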