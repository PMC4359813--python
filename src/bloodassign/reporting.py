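"""Run artifacts: CSV outputs, the reproducibility manifest, and plots."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .blood_types import TYPE_ORDER
from .demand import ScenarioConfig, config_to_dict
from .simulator import RunResult, records_to_frame

__all__ = ["RunManifest", "write_run", "plot_run"]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config: dict
    seed: int
    mode: str
    outputs: Dict[str, str]
    timestamp: str
    version: str

    @classmethod
    def for_run(cls, cfg: ScenarioConfig, mode: str, outputs: Dict[str, str]) -> "RunManifest":
        return cls(
            config=config_to_dict(cfg),
            seed=cfg.seed,
            mode=mode,
            outputs=outputs,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            version=__version__,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def write_run(
    result: RunResult, cfg: ScenarioConfig, mode: str, outdir
) -> Dict[str, Path]:
    """Write daily.csv, summary.csv, trace.csv (pso mode) and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "daily": outdir / "daily.csv",
        "summary": outdir / "summary.csv",
        "manifest": outdir / "manifest.json",
    }
    records_to_frame(result.records).to_csv(paths["daily"], index=False)
    summary = result.summary.to_frame()
    summary.insert(0, "measure", summary.index)
    summary.to_csv(paths["summary"], index=False)
    if result.trace:
        paths["trace"] = outdir / "trace.csv"
        pd.DataFrame(result.trace, columns=["day", "iterations", "fitness"]).to_csv(
            paths["trace"], index=False
        )
    manifest = RunManifest.for_run(
        cfg, mode, {k: p.name for k, p in paths.items() if k != "manifest"}
    )
    manifest.to_json(paths["manifest"])
    return paths


def plot_run(daily_csv, outdir, fmt: str = "png") -> List[Path]:
    """Render the per-day level curves and the import-to-request ratio bars.

    Curves show, per day, the bank-wide totals of units available,
    requested, supplied and imported (summed over types, values straight
    from the CSV, no smoothing); the bar chart shows Σ imported / Σ
    requested per type plus the overall ratio.
    """
    daily = pd.read_csv(daily_csv)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    totals = daily.groupby("day")[["available", "requested", "supplied", "imported"]].sum()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for col in totals.columns:
        ax.plot(totals.index, totals[col], label=col)
    ax.set_xlabel("day")
    ax.set_ylabel("blood units")
    ax.set_title("Daily bank-wide volumes")
    ax.legend()
    fig.tight_layout()
    p = outdir / f"levels.{fmt}"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    by_type = daily.groupby("type")[["requested", "imported"]].sum()
    by_type = by_type.reindex([t.label for t in TYPE_ORDER])
    ratio = (by_type["imported"] / by_type["requested"].replace(0, pd.NA)).fillna(0.0)
    overall = by_type["imported"].sum() / max(by_type["requested"].sum(), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(list(ratio.index) + ["all"], list(ratio) + [overall])
    ax.set_ylabel("imported / requested")
    ax.set_title("Import-to-request ratio")
    fig.tight_layout()
    p = outdir / f"import_ratio.{fmt}"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)
    return written
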