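"""Grid-level aggregation and rendering of summary artifacts.

Aggregates per-recording analyses over the 5 x 8 x 8 stimulation grid into
per-cell summaries (event counts, dynamic-range growth, mean phase
asymmetry) and a per-SLN table (included conditions, signals with mode
changes, maximum changes per signal, mean airflow at the changes), and
renders heatmaps, per-recording trace plots and acoustic spectrograms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_preprocess import AcousticRecord, Condition
from .pipeline import AnalysisResult, grid_events_table

__all__ = [
    "ConditionSummary",
    "summarize_grid",
    "spectrogram",
    "render_outputs",
    "plot_recording",
]


@dataclass
class ConditionSummary:
    """Per-cell aggregate of one stimulation condition."""

    sln: int
    rln_left: int
    rln_right: int
    included: bool
    n_events: int = 0
    dr_slope: float = np.nan
    mean_pha: float = np.nan
    mean_flow_at_events: float = np.nan


def _dr_slope(params: pd.DataFrame) -> float:
    """Least-squares slope of per-cycle dynamic range vs cycle time
    (pixel^2 per second); NaN with fewer than two valid cycles."""
    valid = params[params["valid"]].dropna(subset=["dr"])
    if len(valid) < 2:
        return np.nan
    return float(np.polyfit(valid["time_s"], valid["dr"], 1)[0])


def summarize_grid(
    results: Mapping[Condition, AnalysisResult | None]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate grid results into (per-cell table, per-SLN table).

    The per-SLN table mirrors the classic overview: number of included
    conditions, number of signals with at least one mode change, maximum
    changes in a single signal, and mean airflow at the changes.
    """
    cells = []
    for cond, res in results.items():
        summary = ConditionSummary(*cond, included=False)
        if res is not None and res.included:
            summary.included = True
            summary.n_events = res.n_events
            summary.dr_slope = _dr_slope(res.params)
            valid = res.params[res.params["valid"]]
            summary.mean_pha = float(valid["pha"].mean())
            if res.events:
                summary.mean_flow_at_events = float(
                    np.mean([ev.flow_at_event for ev in res.events])
                )
        cells.append(summary.__dict__)
    per_cell = pd.DataFrame(cells)

    rows = []
    for sln, grp in per_cell.groupby("sln"):
        with_events = grp[grp["n_events"] > 0]
        flows = with_events["mean_flow_at_events"].dropna()
        rows.append(
            {
                "sln": sln,
                "included_conditions": int(grp["included"].sum()),
                "signals_with_changes": int(len(with_events)),
                "max_changes_per_signal": (
                    int(grp["n_events"].max()) if len(with_events) else 0
                ),
                "mean_flow_at_change": float(flows.mean()) if len(flows) else np.nan,
            }
        )
    return per_cell, pd.DataFrame(rows)


def spectrogram(
    acoustic: AcousticRecord, window: int = 4096, overlap: float = 0.80
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude of the acoustic channel.

    Hann window of ``window`` samples, hop ``round(window * (1 - overlap))``
    (819 samples for the default 4096 / 80%).  Returns ``(freqs, times, S)``
    with ``S`` of shape (freqs, frames).  Raises ``ValueError`` for records
    shorter than one window.
    """
    from scipy.signal import spectrogram as _sp

    x = acoustic.samples
    if len(x) < window:
        raise ValueError(
            f"record of {len(x)} samples is shorter than the {window}-sample window"
        )
    hop = int(round(window * (1.0 - overlap)))
    f, t, S = _sp(
        x,
        fs=acoustic.sample_rate,
        window="hann",
        nperseg=window,
        noverlap=window - hop,
        mode="magnitude",
        detrend=False,
    )
    return f, t, S


def _heatmap_matrices(per_cell: pd.DataFrame, column: str) -> dict[int, np.ndarray]:
    """8 x 8 (rln_left x rln_right) matrix of ``column`` per SLN level."""
    out = {}
    for sln, grp in per_cell.groupby("sln"):
        m = np.full((8, 8), np.nan)
        for _, row in grp.iterrows():
            if row["included"]:
                m[int(row["rln_left"]), int(row["rln_right"])] = row[column]
        out[int(sln)] = m
    return out


def plot_recording(result: AnalysisResult, path: str | Path) -> Path:
    """GAW trace, LF0 with event markers, and AP/TP for one recording."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = result.record
    fig, axes = plt.subplots(3, 1, figsize=(10, 8), sharex=True)
    axes[0].plot(rec.times(), rec.total, lw=0.5, color="k")
    axes[0].set_ylabel("glottal area (px$^2$)")
    if rec.damaged_mask.any():
        axes[0].fill_between(
            rec.times(), 0, rec.total.max(), where=rec.damaged_mask,
            color="red", alpha=0.2, label="damaged",
        )
    if result.params is not None:
        valid = result.params[result.params["valid"]]
        axes[1].plot(valid["time_s"], valid["lf0"], ".", ms=2, label="LF0")
        if result.lf0_smooth is not None:
            idx = result.lf0_smooth.index
            tmap = result.params.set_index("cycle_index")["time_s"]
            axes[1].plot(tmap.loc[idx], result.lf0_smooth.values,
                         "-", lw=1.5, label="smoothed")
        axes[2].plot(valid["time_s"], valid["ap"], ".", ms=2, label="AP")
        axes[2].plot(valid["time_s"], valid["tp"], ".", ms=2, label="TP")
    for ev in result.events:
        for ax in axes[:2]:
            ax.axvline(ev.event_time, color="tab:red", ls="--", lw=1)
    axes[1].set_ylabel("LF0 (Hz)")
    axes[2].set_ylabel("periodicity")
    axes[2].set_xlabel("time (s)")
    for ax in axes[1:]:
        ax.legend(loc="best", fontsize=8)
    fig.suptitle(rec.recording_id)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_outputs(
    results: Mapping[Condition, AnalysisResult | None],
    out_dir: str | Path,
    plots: bool | Sequence[Condition] = False,
) -> dict[str, Path]:
    """Write the grid's tables, per-cell JSON and heatmap figures.

    ``plots`` selects per-recording trace plots: ``True`` for every included
    recording with events, or an explicit list of conditions.  File naming
    is deterministic.  Returns the paths written keyed by artifact name.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_cell, per_sln = summarize_grid(results)
    events = grid_events_table(results)

    written: dict[str, Path] = {}
    for name, df in (("per_cell", per_cell), ("per_sln", per_sln),
                     ("events", events)):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    p = out_dir / "per_cell.json"
    p.write_text(json.dumps(per_cell.to_dict(orient="records"), indent=1,
                            default=float))
    written["per_cell_json"] = p

    specs = {
        "n_events": ("Mode changes", "Reds"),
        "dr_slope": ("DR increase over time (px$^2$/s)", "Reds"),
        "mean_pha": ("Phase asymmetry (red: left lead)", "RdYlGn_r"),
    }
    for column, (title, cmap) in specs.items():
        mats = _heatmap_matrices(per_cell, column)
        fig, axes = plt.subplots(1, len(mats), figsize=(3.2 * len(mats), 3.4))
        axes = np.atleast_1d(axes)
        vals = np.concatenate([m[np.isfinite(m)] for m in mats.values()] or [[0]])
        vmax = float(np.max(np.abs(vals))) if len(vals) else 1.0
        vmin = -vmax if column == "mean_pha" else 0.0
        for ax, (sln, m) in zip(axes, sorted(mats.items())):
            im = ax.imshow(m, origin="lower", cmap=cmap, vmin=vmin, vmax=vmax)
            ax.set_title(f"SLN {sln}", fontsize=9)
            ax.set_xlabel("RLN right")
            if sln == min(mats):
                ax.set_ylabel("RLN left")
        fig.colorbar(im, ax=axes, shrink=0.8)
        fig.suptitle(title)
        p = out_dir / f"heatmap_{column}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written[f"heatmap_{column}"] = p

    if plots:
        todo = (
            [c for c, r in results.items() if r is not None and r.events]
            if plots is True
            else list(plots)
        )
        for cond in todo:
            res = results[cond]
            if res is None:
                continue
            p = out_dir / "recordings" / f"{res.record.recording_id}.png"
            plot_recording(res, p)
            written[f"plot_{res.record.recording_id}"] = p
    return written
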