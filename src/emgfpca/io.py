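"""Reading and writing the pipeline's tabular and result formats.

The canonical exchange format is a long CSV with one row per sample:
``subject, group, leg, muscle, trial, sample, value`` plus a per-trial
sampling-rate column ``fs`` (constant within a trial).  A column map adapts
vendor exports with different headers.  Results are written as CSV tables
plus one JSON document per functional-PCA fit, and a run-metadata file that
doubles as the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import CANONICAL_COLUMNS, GROUPS, LEGS
from .exceptions import IntegrityError, SchemaError

# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

STAGES = ("raw", "envelope", "normalized")


@dataclass
class EmgRecording:
    """One trial of one muscle: a sampled signal plus its provenance.

    ``stage`` tracks where the trial sits in the processing chain:
    ``raw`` (possibly conditioned) voltage samples, ``envelope`` after
    rectification and low-pass smoothing, ``normalized`` once resampled to
    the common cycle grid and amplitude-normalized.
    """

    subject_id: str
    group: str
    leg: str
    muscle: str
    trial: int
    fs: float
    samples: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.leg not in LEGS:
            raise ValueError(f"leg must be one of {LEGS}, got {self.leg!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.trial < 1:
            raise ValueError("trial index must be >= 1")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.group, self.leg, self.muscle, self.trial)

    def replace(self, **kw) -> "EmgRecording":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# long-CSV input
# ---------------------------------------------------------------------------

def read_emg_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    stage: str = "raw",
) -> list[EmgRecording]:
    """Read a long-format CSV into a list of :class:`EmgRecording`.

    Parameters
    ----------
    path:
        CSV file with a header row, one row per sample.
    schema:
        Optional map from canonical column name (``subject``, ``group``,
        ``leg``, ``muscle``, ``trial``, ``sample``, ``value``, ``fs``) to
        the actual header in the file.
    stage:
        Stage label assigned to every trial unless the file carries a
        ``stage`` column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    df = df.rename(columns=rename)

    required = list(CANONICAL_COLUMNS) + ["fs"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    bad_groups = set(df["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValueError(
            f"unknown group token(s) {sorted(bad_groups)}; accepted: {list(GROUPS)}"
        )
    bad_legs = set(df["leg"].unique()) - set(LEGS)
    if bad_legs:
        raise ValueError(
            f"unknown leg token(s) {sorted(bad_legs)}; accepted: {list(LEGS)}"
        )

    has_stage = "stage" in df.columns
    recordings: list[EmgRecording] = []
    keys = ["subject", "group", "leg", "muscle", "trial"]
    for (subj, group, leg, muscle, trial), g in df.groupby(keys, sort=True):
        g = g.sort_values("sample")
        fs_vals = g["fs"].unique()
        if len(fs_vals) != 1:
            raise IntegrityError(
                f"mixed sampling rates {sorted(fs_vals)} within trial "
                f"{(subj, muscle, leg, trial)}"
            )
        trial_stage = str(g["stage"].iloc[0]) if has_stage else stage
        recordings.append(
            EmgRecording(
                subject_id=str(subj),
                group=str(group),
                leg=str(leg),
                muscle=str(muscle),
                trial=int(trial),
                fs=float(fs_vals[0]),
                samples=g["value"].to_numpy(dtype=float),
                stage=trial_stage,
            )
        )
    return recordings


def recordings_to_frame(recordings: Iterable[EmgRecording]) -> pd.DataFrame:
    """Inverse of :func:`read_emg_table`: long DataFrame, one row per sample."""
    parts = []
    for rec in recordings:
        n = rec.samples.size
        parts.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "group": rec.group,
                    "leg": rec.leg,
                    "muscle": rec.muscle,
                    "trial": rec.trial,
                    "sample": np.arange(n),
                    "value": rec.samples,
                    "fs": rec.fs,
                    "stage": rec.stage,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_emg_table(recordings: Iterable[EmgRecording], path: str | Path) -> None:
    recordings_to_frame(recordings).to_csv(path, index=False, float_format="%.17g")


def read_events_table(path: str | Path) -> pd.DataFrame:
    """Read per-trial cycle-event annotations (sample indices).

    Columns: ``subject, trial, cycle_start, p1_p2, p2_p3, p3_p4, cycle_end``
    (the three internal boundaries are optional).
    """
    df = pd.read_csv(path)
    required = ["subject", "trial", "cycle_start", "cycle_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"events file missing column(s): {missing}")
    return df


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------

@dataclass
class ResultsBundle:
    """Everything one run produces, ready for serialization."""

    iemg: pd.DataFrame | None = None
    delta_iemg: pd.DataFrame | None = None
    fpca: dict = field(default_factory=dict)     # (muscle, leg) -> FpcaResult
    stats: pd.DataFrame | None = None
    reliability: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)   # e.g. discriminant screening


def write_results(bundle: ResultsBundle, path: str | Path) -> list[str]:
    """Write a :class:`ResultsBundle` to ``path``; return the manifest.

    One CSV per table, one JSON per FPCA fit, plus ``run_metadata.json``
    containing the config echo and the manifest itself.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    tables = {
        "iemg.csv": bundle.iemg,
        "delta_iemg.csv": bundle.delta_iemg,
        "stats.csv": bundle.stats,
        "reliability.csv": bundle.reliability,
    }
    for name, df in tables.items():
        if df is not None:
            df.to_csv(out / name, index=False, float_format="%.17g")
            manifest.append(name)

    for (muscle, leg), result in sorted(bundle.fpca.items()):
        name = f"fpca_{muscle}_{leg}.json"
        (out / name).write_text(json.dumps(result.to_dict(), indent=1))
        manifest.append(name)

    meta = {"config": bundle.config, "extras": bundle.extras,
            "files": sorted(manifest)}
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    return sorted(manifest)


def read_fpca_json(path: str | Path):
    from .fpca import FpcaResult

    return FpcaResult.from_dict(json.loads(Path(path).read_text()))
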