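"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-separated with a one-line ``#`` header comment stating the
position convention (1-based along the transcript; position 0 is the
total-RNA control readout).  Floats are written with 17 significant digits so
every round trip is exact to double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .kinfit import ControlStats
from .naim import AutocorrResult, Cluster, InterferenceProfile
from .simulate import GelDataset

__all__ = [
    "write_gel",
    "read_gel",
    "write_band_table",
    "read_band_table",
    "write_fits",
    "read_fits",
    "write_control_stats",
    "read_control_stats",
    "write_profile",
    "read_profile",
    "write_clusters",
    "write_autocorr",
]

_FLOAT_FMT = "%.17g"
_HEADER = "# positions are 1-based along the transcript; position 0 = total-RNA control\n"


def _write_tsv(df: pd.DataFrame, path: Path | str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def _sidecar(path: Path | str) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.json")


def write_gel(dataset: GelDataset, path: Path | str) -> None:
    """Write the long-format band table plus a metadata sidecar JSON."""
    _write_tsv(dataset.frame, path)
    with open(_sidecar(path), "w") as fh:
        json.dump(dataset.metadata, fh, indent=2, default=str)
        fh.write("\n")


def read_gel(path: Path | str) -> GelDataset:
    frame = _read_tsv(path)
    meta_path = _sidecar(path)
    metadata = {}
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
    return GelDataset(frame=frame, metadata=metadata)


def write_band_table(table: pd.Series, path: Path | str) -> None:
    df = pd.DataFrame(
        {"position": table.index.to_numpy(), "intensity": table.to_numpy()}
    )
    _write_tsv(df, path)


def read_band_table(path: Path | str) -> pd.Series:
    df = _read_tsv(path)
    return df.set_index("position")["intensity"]


def write_fits(profile: pd.DataFrame, path: Path | str) -> None:
    _write_tsv(profile, path)


def read_fits(path: Path | str) -> pd.DataFrame:
    return _read_tsv(path)


def write_control_stats(stats: ControlStats, path: Path | str) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2) + "\n")


def read_control_stats(path: Path | str) -> ControlStats:
    return ControlStats.from_dict(json.loads(Path(path).read_text()))


def write_profile(profile: InterferenceProfile, path: Path | str) -> None:
    _write_tsv(profile.to_frame(), path)


def read_profile(path: Path | str, threshold: float = 2.5) -> InterferenceProfile:
    return InterferenceProfile.from_frame(_read_tsv(path), threshold=threshold)


def write_clusters(clusters: list[Cluster], path: Path | str) -> None:
    df = pd.DataFrame(
        [
            {"start": c.start, "end": c.end, "center": c.center, "peak_lambda": c.peak}
            for c in clusters
        ],
        columns=["start", "end", "center", "peak_lambda"],
    )
    _write_tsv(df, path)


def write_autocorr(result: AutocorrResult, path: Path | str) -> None:
    df = pd.DataFrame({"lag": result.lags, "acf": result.acf})
    _write_tsv(df, path)
    meta = {
        "step_size": result.step_size,
        "peak_value": result.peak_value,
        "significant": bool(result.significant),
        "threshold": result.threshold,
        "message": result.message,
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
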