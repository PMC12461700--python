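"""Model–data agreement measures and tidy exports.

Power-domain fit: per participant, the mean squared error between the
z-scored EEG power and a model's z-scored power over the 5 tempi x 4
frequency categories (EEG averaged over attention conditions first).
Phase-domain fit: squared error of each participant's PCM against each
model's PCM. Inferential statistics (mixed models, Bayesian t-tests) are
not re-implemented; the tidy tables are written for external statistics
software.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import CATEGORIES

POWER_COLUMNS = ("participant", "tempo_ms", "condition", "category", "z")
MODEL_COLUMNS = ("tempo_ms", "category", "z")


def tidy_power_table(rows: dict, participant=None, condition=None) -> pd.DataFrame:
    """Assemble {tempo_ms: category->z Series} into a tidy table."""
    records = []
    for tempo, series in rows.items():
        for category, z in series.items():
            rec = {"tempo_ms": tempo, "category": category, "z": float(z)}
            if participant is not None:
                rec["participant"] = participant
            if condition is not None:
                rec["condition"] = condition
            records.append(rec)
    return pd.DataFrame(records)


def _model_grid(model_table: pd.DataFrame) -> pd.Series:
    m = model_table.set_index(["tempo_ms", "category"])["z"]
    if m.index.has_duplicates:
        raise ValueError("duplicate (tempo, category) cells in model table")
    return m


def power_mse(eeg_table: pd.DataFrame, model_table: pd.DataFrame) -> pd.Series:
    """Per-participant MSE between z-scored EEG and model power.

    ``eeg_table`` is tidy (participant, tempo_ms, condition, category, z);
    it is averaged over conditions before comparison. ``model_table`` is
    tidy (tempo_ms, category, z). Both must cover the same
    (tempo x category) cells.
    """
    model = _model_grid(model_table)
    avg = (
        eeg_table.groupby(["participant", "tempo_ms", "category"])["z"]
        .mean()
        .reset_index()
    )
    out = {}
    for participant, grp in avg.groupby("participant"):
        cells = grp.set_index(["tempo_ms", "category"])["z"]
        if set(cells.index) != set(model.index):
            raise ValueError(
                f"participant {participant}: (tempo, category) cells do not "
                "match the model table"
            )
        diff = cells - model.reindex(cells.index)
        out[participant] = float((diff**2).mean())
    return pd.Series(out, name="mse")


def pcm_errors(participant_pcms, pcm_oscillator: float,
               pcm_evoked: float) -> pd.DataFrame:
    """Squared error of each participant's PCM against each model's PCM."""
    pcms = pd.Series(participant_pcms, dtype=float)
    for name, v in [("oscillator", pcm_oscillator), ("evoked", pcm_evoked)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} PCM outside [0, 1]")
    if ((pcms < 0) | (pcms > 1)).any():
        raise ValueError("participant PCM outside [0, 1]")
    return pd.DataFrame(
        {
            "pcm": pcms,
            "se_oscillator": (pcms - pcm_oscillator) ** 2,
            "se_evoked": (pcms - pcm_evoked) ** 2,
        }
    )


def summarize_fit(mse_oscillator: pd.Series, mse_evoked: pd.Series) -> pd.DataFrame:
    """Group mean/sd of the per-participant power-domain errors."""
    return pd.DataFrame(
        {
            "model": ["oscillator", "evoked"],
            "mean_mse": [mse_oscillator.mean(), mse_evoked.mean()],
            "sd_mse": [mse_oscillator.std(ddof=1), mse_evoked.std(ddof=1)],
        }
    )


def export_stats_tables(results: dict, outdir: str | Path) -> dict:
    """Write tidy CSVs for external inferential statistics.

    ``results`` may contain: ``power`` (tidy participant power table),
    ``model_power`` (tidy model table per model), ``mse`` (per-participant
    errors), ``pcm`` (per-participant PCM + squared errors), ``itc``
    (tidy ITC table). Returns {name: written path}. Raises if no table is
    present (incomplete pipeline state).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    known = ("power", "model_power", "mse", "pcm", "itc")
    for name in known:
        if name not in results or results[name] is None:
            continue
        obj = results[name]
        path = outdir / f"{name}.csv"
        if isinstance(obj, pd.Series):
            obj = obj.rename_axis("participant").reset_index()
        obj.to_csv(path, index=False)
        written[name] = path
    if not written:
        raise ValueError("incomplete pipeline state: nothing to export")
    return written
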