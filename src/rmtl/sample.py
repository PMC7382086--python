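"""Subject-level competing-risks data: container, validation and CSV I/O.

A record is a triple (time, status, group): ``time`` is the observed follow-up
time, ``status`` codes the outcome (0 = censored, 1 = event of interest,
2 = competing event; larger integer codes are tolerated for multi-cause data),
and ``group`` is an optional arm label used by the two-sample procedures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CompetingRisksSample", "read_sample", "write_sample"]

CENSORED = 0
EVENT_OF_INTEREST = 1
COMPETING_EVENT = 2


@dataclass(frozen=True)
class CompetingRisksSample:
    """One group's (or one study's) competing-risks records.

    Parameters
    ----------
    times
        Non-negative observed times, one per subject.
    causes
        Integer outcome codes aligned with ``times``; 0 means censored.
    group
        Optional label identifying the arm these records belong to.
    """

    times: np.ndarray
    causes: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        causes = np.asarray(self.causes, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "causes", causes)
        if times.ndim != 1 or causes.ndim != 1 or times.shape != causes.shape:
            raise ValueError("times and causes must be 1-d arrays of equal length")
        if times.size == 0:
            raise ValueError("sample must contain at least one record")
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise ValueError("all times must be finite and non-negative")
        if np.any(causes < 0):
            raise ValueError("cause codes must be non-negative integers")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def max_time(self) -> float:
        return float(self.times.max())

    def n_events(self, cause: int) -> int:
        return int(np.sum(self.causes == cause))

    def censoring_rate(self) -> float:
        return float(np.mean(self.causes == CENSORED))

    def last_event_time(self, cause: int = EVENT_OF_INTEREST) -> float:
        """Largest observed time carrying an event of the given cause."""
        mask = self.causes == cause
        if not mask.any():
            raise ValueError(
                f"group {self.group!r} has no events of cause {cause}; "
                "supply tau explicitly"
            )
        return float(self.times[mask].max())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "status": self.causes})
        if self.group is not None:
            df["group"] = self.group
        return df


def _validate_frame(df: pd.DataFrame, path: str) -> None:
    for col in ("time", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    bad_time = df.index[~np.isfinite(df["time"]) | (df["time"] < 0)]
    if len(bad_time):
        rows = ", ".join(str(i + 2) for i in bad_time[:5])  # +2: header + 1-based
        raise ValueError(f"{path}: invalid time on line(s) {rows}")
    status = df["status"]
    bad_status = df.index[(status != status.astype(int)) | (status < 0) | (status > 2)]
    if len(bad_status):
        rows = ", ".join(str(i + 2) for i in bad_status[:5])
        raise ValueError(
            f"{path}: status must be 0 (censored), 1 (event of interest) or "
            f"2 (competing event); bad value on line(s) {rows}"
        )


def read_sample(
    path: str,
    *,
    time_col: str = "time",
    status_col: str = "status",
    group_col: str | None = "group",
    sep: str = ",",
) -> CompetingRisksSample | tuple[CompetingRisksSample, CompetingRisksSample]:
    """Read subject-level records from a delimited text file.

    Returns a single :class:`CompetingRisksSample` when the file carries no
    group column, or a pair of samples (ordered lexicographically by group
    label) when it does. Files with more than two group levels are rejected.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df = df.rename(columns={time_col: "time", status_col: "status"})
    if group_col is not None and group_col in df.columns and group_col != "group":
        df = df.rename(columns={group_col: "group"})
    _validate_frame(df, str(path))

    if group_col is None or "group" not in df.columns:
        return CompetingRisksSample(df["time"].to_numpy(), df["status"].to_numpy())

    labels = sorted(df["group"].astype(str).unique())
    if len(labels) > 2:
        raise ValueError(
            f"{path}: expected at most two groups, found {len(labels)}: {labels}"
        )
    if len(labels) == 1:
        sub = df
        return CompetingRisksSample(
            sub["time"].to_numpy(), sub["status"].to_numpy(), group=labels[0]
        )
    out = []
    for lab in labels:
        sub = df[df["group"].astype(str) == lab]
        out.append(
            CompetingRisksSample(
                sub["time"].to_numpy(), sub["status"].to_numpy(), group=lab
            )
        )
    return out[0], out[1]


def write_sample(
    path: str, *samples: CompetingRisksSample, sep: str = ","
) -> None:
    """Write one or more groups of records to a delimited text file."""
    frames = []
    for i, s in enumerate(samples):
        df = s.to_frame()
        if "group" not in df.columns and len(samples) > 1:
            df["group"] = str(i + 1)
        frames.append(df)
    # %.17g guarantees float64 values survive a write/read round trip exactly
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )
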