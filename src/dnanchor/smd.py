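"""Steered-MD pull-out record analysis.

A constant-velocity steered-MD run logs, per frame, the time, the CoM z
coordinate of the pulled group (here the terminal three base pairs) and
the spring force along the pulling direction.  This module bins the
force along z (2 Å bins by default), integrates the cumulative work
W(z) = ∫ F dz by the trapezoidal rule, and ranks constructs by total
pull-out work.  Work is reported in pN·Å and in kcal/mol
(1 kcal/(mol·Å) = 69.479 pN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PN_PER_KCAL_MOL_A",
    "SMDRecord",
    "ForceProfile",
    "WorkCurve",
    "read_smd",
    "write_smd",
    "bin_force",
    "work_curve",
    "rank_constructs",
]

#: 1 kcal/(mol·Å) expressed in pN.
PN_PER_KCAL_MOL_A = 69.479

_REQUIRED_COLUMNS = ("time_ns", "z_A", "force_pN")


@dataclass
class SMDRecord:
    """Per-frame (time, CoM z, force) record of one pull."""

    times: np.ndarray  # ns
    z: np.ndarray  # Å
    force: np.ndarray  # pN, positive = away from the membrane
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (self.times.shape == self.z.shape == self.force.shape):
            raise ValueError("times, z and force must have equal lengths")
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("record must contain at least one frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("record times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ForceProfile:
    """Mean force in contiguous z bins; only occupied bins are reported."""

    z_bin_centers: np.ndarray  # Å
    mean_force: np.ndarray  # pN
    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(self.counts < 1):
            raise ValueError("reported bins must contain at least one sample")


@dataclass
class WorkCurve:
    """Cumulative work along z, in pN·Å and kcal/mol."""

    z: np.ndarray  # Å
    work_pN_A: np.ndarray
    label: str = ""

    @property
    def work_kcal_mol(self) -> np.ndarray:
        return self.work_pN_A / PN_PER_KCAL_MOL_A

    @property
    def total_pN_A(self) -> float:
        return float(self.work_pN_A[-1])

    @property
    def total_kcal_mol(self) -> float:
        return self.total_pN_A / PN_PER_KCAL_MOL_A

    def work_at(self, z_query: float) -> float:
        """Work (pN·Å) at an arbitrary z by linear interpolation."""
        return float(np.interp(z_query, self.z, self.work_pN_A))


def read_smd(path: str | Path, label: str = "") -> SMDRecord:
    """Read a pull record from TSV with columns time_ns, z_A, force_pN."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return SMDRecord(
        times=df["time_ns"].to_numpy(),
        z=df["z_A"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        label=label or path.stem,
    )


def write_smd(record: SMDRecord, path: str | Path) -> None:
    """Write a pull record as TSV (columns time_ns, z_A, force_pN)."""
    pd.DataFrame(
        {"time_ns": record.times, "z_A": record.z, "force_pN": record.force}
    ).to_csv(path, sep="\t", index=False)


def bin_force(record: SMDRecord, bin_width: float = 2.0) -> ForceProfile:
    """Average the sampled force in contiguous z bins (default 2 Å).

    Bin edges are aligned to multiples of the bin width; a sample at z
    falls in the bin [edge, edge + bin_width).  Empty bins are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if record.z.max() - record.z.min() < 0 or len(record) == 0:
        raise ValueError("empty record")
    first_edge = np.floor(record.z.min() / bin_width) * bin_width
    idx = np.floor((record.z - first_edge) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=record.force, minlength=n_bins)
    occupied = counts > 0
    centers = first_edge + (np.arange(n_bins)[occupied] + 0.5) * bin_width
    return ForceProfile(
        z_bin_centers=centers,
        mean_force=sums[occupied] / counts[occupied],
        counts=counts[occupied],
        bin_width=bin_width,
    )


def _smooth_z(record: SMDRecord, window_ns: float) -> np.ndarray:
    if len(record) < 3:
        return record.z
    dt = np.median(np.diff(record.times))
    w = max(1, int(round(window_ns / dt)))
    if w <= 1:
        return record.z
    kernel = np.ones(w) / w
    pad = np.concatenate([np.full(w // 2, record.z[0]), record.z, np.full(w - 1 - w // 2, record.z[-1])])
    return np.convolve(pad, kernel, mode="valid")


def work_curve(
    record: SMDRecord,
    smooth_ns: float = 1.0,
    monotone_tol: float = 1e-9,
) -> WorkCurve:
    """Cumulative trapezoidal work W(z) = ∫ F dz along the pull.

    The raw z trace of a constant-velocity pull should be monotone up to
    thermal noise; if it is not, it is checked again after a moving
    average over ``smooth_ns``.  A trace that remains non-monotone is
    rejected (integrating work against a backtracking coordinate is
    ambiguous).
    """
    z = record.z
    if len(record) < 2:
        raise ValueError("need at least two samples to integrate work")
    if np.any(np.diff(z) < -monotone_tol):
        z_s = _smooth_z(record, smooth_ns)
        if np.any(np.diff(z_s) < -monotone_tol):
            raise ValueError(
                "z is not monotone non-decreasing even after "
                f"{smooth_ns} ns smoothing; smooth the record or check the "
                "force log"
            )
    work = cumulative_trapezoid(record.force, record.z, initial=0.0)
    return WorkCurve(z=record.z.copy(), work_pN_A=work, label=record.label)


def rank_constructs(curves: list[WorkCurve]) -> list[tuple[str, float, int]]:
    """Rank constructs by total pull-out work, largest first.

    Returns (label, total work pN·Å, rank) with rank 1 for the hardest
    pull; exact ties in total work are broken by the work at the
    midpoint of the common z range, and constructs still tied share a
    rank.  Curves must overlap in z.
    """
    if len(curves) < 2:
        raise ValueError("need at least two work curves to rank")
    lo = max(float(c.z[0]) for c in curves)
    hi = min(float(c.z[-1]) for c in curves)
    if hi <= lo:
        raise ValueError("work curves have non-overlapping z ranges")
    z_mid = 0.5 * (lo + hi)
    keyed = [
        (c.label or f"curve{i}", c.total_pN_A, c.work_at(z_mid)) for i, c in enumerate(curves)
    ]
    keyed.sort(key=lambda t: (-t[1], -t[2]))
    ranked: list[tuple[str, float, int]] = []
    for pos, (label, total, mid) in enumerate(keyed):
        if pos > 0 and (total, mid) == (keyed[pos - 1][1], keyed[pos - 1][2]):
            rank = ranked[-1][2]  # tie: share rank
        else:
            rank = pos + 1
        ranked.append((label, total, rank))
    return ranked
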