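"""Recording-bundle readers/writers and the accuracy-report aggregator.

A bundle is a directory of plain-text artifacts:

* ``eeg.csv``   — time + 8 named EEG columns, microvolts
* ``nirs.csv``  — time + 24 columns ``ch01_760 .. ch12_830``, raw intensities
* ``events.tsv``— BIDS-style onset/duration/trial_type
* ``meta.json`` — rates, wavelengths, montage (3 sources x 8 detectors
  pairing into 12 channels), seed and a config echo
* ``ground_truth.csv`` (optional) — simulated HbO/HbR truth, micromolar

Values round-trip losslessly (written with 17 significant digits).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import montage, paradigm
from .errors import ChannelCountError, InvalidArgumentError, MalformedHeaderError, MissingFileError
from .simulate import Recording, SimulationConfig

_FLOAT = "%.17g"

PROBLEM_COLUMNS = ("Left vs Stop", "Right vs Stop", "Forward vs Stop", "Back vs Stop")


def write_bundle(
    recording: Recording,
    path: str | Path,
    config: SimulationConfig | None = None,
    include_truth: bool = True,
) -> Path:
    """Write a recording bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    n_eeg = recording.eeg.shape[0]
    eeg_frame = pd.DataFrame(recording.eeg, columns=list(recording.eeg_channels))
    eeg_frame.insert(0, "time", np.arange(n_eeg) / recording.eeg_rate)
    eeg_frame.to_csv(path / "eeg.csv", index=False, float_format=_FLOAT)

    n_nirs = recording.nirs_intensity.shape[0]
    flat = recording.nirs_intensity.reshape(n_nirs, -1)
    nirs_frame = pd.DataFrame(flat, columns=montage.nirs_column_names())
    nirs_frame.insert(0, "time", np.arange(n_nirs) / recording.nirs_rate)
    nirs_frame.to_csv(path / "nirs.csv", index=False, float_format=_FLOAT)

    paradigm.write_events(recording.schedule, path / "events.tsv")

    meta = {
        "eeg_rate": recording.eeg_rate,
        "nirs_rate": recording.nirs_rate,
        "wavelengths_nm": list(recording.wavelengths),
        "n_samples": recording.schedule.n_samples,
        "seed": recording.seed,
        "montage": {
            "eeg_channels": list(recording.eeg_channels),
            "nirs_channels": montage.N_NIRS_CHANNELS,
            "nirs_sources": montage.N_NIRS_SOURCES,
            "nirs_detectors": montage.N_NIRS_DETECTORS,
            "nirs_pairs": [list(p) for p in montage.NIRS_PAIRS],
        },
        "config": asdict(config) if config is not None else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))

    if include_truth and recording.truth_hbo is not None:
        truth = pd.DataFrame(
            np.hstack([recording.truth_hbo, recording.truth_hbr]),
            columns=[f"{ch}_hbo" for ch in montage.NIRS_CHANNEL_NAMES]
            + [f"{ch}_hbr" for ch in montage.NIRS_CHANNEL_NAMES],
        )
        truth.insert(0, "time", np.arange(n_nirs) / recording.nirs_rate)
        truth.to_csv(path / "ground_truth.csv", index=False, float_format=_FLOAT)
    return path


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingFileError(f"bundle file missing: {path}")
    return path


def read_bundle(path: str | Path) -> Recording:
    """Read a bundle back into a Recording (lossless round trip)."""
    path = Path(path)
    meta = json.loads(_require(path / "meta.json").read_text())
    eeg_frame = pd.read_csv(_require(path / "eeg.csv"), float_precision="round_trip")
    nirs_frame = pd.read_csv(_require(path / "nirs.csv"), float_precision="round_trip")
    schedule = paradigm.read_events(
        _require(path / "events.tsv"), n_samples=meta.get("n_samples")
    )

    expected_eeg = ["time"] + list(meta["montage"]["eeg_channels"])
    if list(eeg_frame.columns) != expected_eeg:
        raise MalformedHeaderError(
            f"eeg.csv header {list(eeg_frame.columns)} != expected {expected_eeg}"
        )
    if len(meta["montage"]["eeg_channels"]) != len(montage.EEG_CHANNELS):
        raise ChannelCountError(
            f"bundle declares {len(meta['montage']['eeg_channels'])} EEG channels, "
            f"expected {len(montage.EEG_CHANNELS)}"
        )
    nirs_cols = [c for c in nirs_frame.columns if c != "time"]
    if "time" not in nirs_frame.columns:
        raise MalformedHeaderError("nirs.csv lacks a time column")
    if len(nirs_cols) != montage.N_NIRS_CHANNELS * 2 or meta["montage"]["nirs_channels"] != 12:
        raise ChannelCountError(
            f"nirs.csv carries {len(nirs_cols)} intensity columns; "
            f"expected {montage.N_NIRS_CHANNELS * 2} (12 channels x 2 wavelengths)"
        )

    n_nirs = len(nirs_frame)
    intensity = nirs_frame[nirs_cols].to_numpy().reshape(n_nirs, montage.N_NIRS_CHANNELS, 2)

    truth_hbo = truth_hbr = None
    truth_path = path / "ground_truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, float_precision="round_trip")
        truth_hbo = truth[[f"{ch}_hbo" for ch in montage.NIRS_CHANNEL_NAMES]].to_numpy()
        truth_hbr = truth[[f"{ch}_hbr" for ch in montage.NIRS_CHANNEL_NAMES]].to_numpy()

    return Recording(
        eeg=eeg_frame[list(meta["montage"]["eeg_channels"])].to_numpy(),
        eeg_rate=float(meta["eeg_rate"]),
        nirs_intensity=intensity,
        nirs_rate=float(meta["nirs_rate"]),
        schedule=schedule,
        wavelengths=tuple(meta["wavelengths_nm"]),
        eeg_channels=tuple(meta["montage"]["eeg_channels"]),
        truth_hbo=truth_hbo,
        truth_hbr=truth_hbr,
        seed=meta.get("seed"),
    )


@dataclass
class AccuracyTable:
    """Per-session accuracies (%) for the four direction-vs-Stop problems."""

    rows: pd.DataFrame  # columns = PROBLEM_COLUMNS, one row per session/subject

    def __post_init__(self) -> None:
        missing = [c for c in PROBLEM_COLUMNS if c not in self.rows.columns]
        if missing:
            raise InvalidArgumentError(f"accuracy table lacks columns {missing}")
        vals = self.rows[list(PROBLEM_COLUMNS)].to_numpy()
        if np.any((vals < 0) | (vals > 100)):
            raise InvalidArgumentError("accuracies must lie in [0, 100]")

    @classmethod
    def from_rows(cls, rows: list[dict | list]) -> "AccuracyTable":
        if rows and not isinstance(rows[0], dict):
            rows = [dict(zip(PROBLEM_COLUMNS, r)) for r in rows]
        return cls(pd.DataFrame(rows, columns=list(PROBLEM_COLUMNS)))


def round_half_up(value: float, decimals: int = 1) -> float:
    """Display rounding, half away from zero (97.45 -> 97.5)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_accuracies(table: AccuracyTable) -> dict[str, dict[str, float]]:
    """Mean and sample SD (n-1) per problem, with 1-decimal display values."""
    if len(table.rows) < 2:
        raise InvalidArgumentError("need at least 2 rows to aggregate")
    out: dict[str, dict[str, float]] = {}
    for col in PROBLEM_COLUMNS:
        vals = table.rows[col].to_numpy(dtype=float)
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        out[col] = {
            "mean": mean,
            "sd": sd,
            "mean_display": round_half_up(mean),
            "sd_display": round_half_up(sd),
        }
    return out


def format_accuracy_report(table: AccuracyTable) -> str:
    """Markdown report: one row per session plus the mean +/- SD summary."""
    lines = ["| Session | " + " | ".join(PROBLEM_COLUMNS) + " |"]
    lines.append("|" + "---|" * (len(PROBLEM_COLUMNS) + 1))
    for i, row in table.rows.iterrows():
        cells = " | ".join(f"{round_half_up(row[c]):.1f}" for c in PROBLEM_COLUMNS)
        lines.append(f"| {i + 1} | {cells} |")
    agg = aggregate_accuracies(table)
    cells = " | ".join(
        f"{agg[c]['mean_display']:.1f} ± {agg[c]['sd_display']:.1f}" for c in PROBLEM_COLUMNS
    )
    lines.append(f"| Mean | {cells} |")
    return "\n".join(lines)
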