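"""DNA duplex distortion metrics: base-pair rise and broken-pair counts.

The *rise* of a base-pair step is taken as the Euclidean distance
between consecutive base-pair centers, each center being the midpoint
of the two paired C1′ atoms.  This deliberately simpler definition (no
full helical reference frame in the 3DNA sense) is exact on ideal
helices and remains well defined on strongly distorted ones; the
canonical B-form value is 3.32 Å per step.

A base pair is counted as *broken* in a frame when its Watson–Crick
donor–acceptor proxy distance (purine N1 to pyrimidine N3) exceeds a
cutoff, 4.5 Å by default — typical heavy-atom hydrogen-bond distances
are 2.8–3.0 Å, and the extra margin absorbs thermal fluctuation without
flagging intact pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dnanchor.io_model import Topology, TrajectorySet

__all__ = [
    "BasePairing",
    "RiseSeries",
    "bp_centers",
    "average_rise",
    "broken_bp_count",
    "DEFAULT_BROKEN_CUTOFF",
]

#: Default Watson–Crick donor–acceptor distance (Å) beyond which a pair
#: counts as broken.
DEFAULT_BROKEN_CUTOFF = 4.5

ResidueKey = tuple[str, int]  # (chain_id, residue_index)


@dataclass(frozen=True)
class BasePairing:
    """Ordered Watson–Crick pairing, 5'→3' along strand 1.

    Each entry pairs a (chain, resid) on strand 1 with its partner on
    strand 2; a residue appears in at most one pair.
    """

    pairs: tuple[tuple[ResidueKey, ResidueKey], ...]

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for res1, res2 in self.pairs:
            for r in (res1, res2):
                if r in seen:
                    raise ValueError(f"residue {r} appears in more than one pair")
                seen.add(r)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_duplex(cls, n_bp: int, chain1: str = "A", chain2: str = "B") -> "BasePairing":
        """Pairing of an antiparallel duplex with both strands numbered
        1..n_bp in their own 5'→3' direction: bp i = (A:i, B:n_bp+1-i)."""
        return cls(
            tuple(
                ((chain1, i), (chain2, n_bp + 1 - i)) for i in range(1, n_bp + 1)
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BasePairing":
        """Read pairing from TSV with columns chain1, resid1, chain2, resid2."""
        df = pd.read_csv(path, sep="\t")
        required = ["chain1", "resid1", "chain2", "resid2"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return cls(
            tuple(
                ((str(r.chain1), int(r.resid1)), (str(r.chain2), int(r.resid2)))
                for r in df.itertuples()
            )
        )


@dataclass
class RiseSeries:
    """Per-frame mean rise, optionally with the full per-step matrix."""

    times: np.ndarray  # ns
    mean_rise: np.ndarray  # Å
    per_step_rise: np.ndarray | None = None  # (n_frames, n_steps)


def _atom_index(topology: Topology, residue: ResidueKey, name: str) -> int:
    mask = (
        (topology.chains == residue[0])
        & (topology.resids == residue[1])
        & (topology.names == name)
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"residue {residue[1]} in chain {residue[0]!r} has no atom {name!r}"
        )
    return int(idx[0])


def _c1_indices(topology: Topology, pairing: BasePairing) -> np.ndarray:
    """(n_pairs, 2) C1' atom indices; raises naming the residue if absent."""
    return np.array(
        [
            (_atom_index(topology, res1, "C1'"), _atom_index(topology, res2, "C1'"))
            for res1, res2 in pairing.pairs
        ],
        dtype=np.intp,
    )


def _wc_proxy_indices(topology: Topology, res1: ResidueKey, res2: ResidueKey) -> tuple[int, int]:
    """Donor/acceptor proxy atoms of one pair: N1 on the purine side,
    N3 on the pyrimidine side (whichever residue carries which)."""
    for don_name, acc_name in (("N1", "N3"), ("N3", "N1")):
        try:
            return _atom_index(topology, res1, don_name), _atom_index(topology, res2, acc_name)
        except ValueError:
            continue
    raise ValueError(
        f"pair {res1} / {res2} lacks N1/N3 Watson-Crick proxy atoms"
    )


def bp_centers(
    topology: Topology, frame_coords: np.ndarray, pairing: BasePairing
) -> np.ndarray:
    """Base-pair centers of one frame: midpoints of the paired C1′ atoms.

    A frayed pair still has a defined center (its midpoint); breakage is
    reported by :func:`broken_bp_count`, not here.
    """
    idx = _c1_indices(topology, pairing)
    coords = np.asarray(frame_coords, dtype=float)
    return 0.5 * (coords[idx[:, 0]] + coords[idx[:, 1]])


def _resolve_window(n_pairs: int, window: Sequence[int] | slice | str | None) -> np.ndarray:
    """Window -> sorted array of 0-based pair indices.

    Accepts None/"all" (every pair), "terminal:k" (last k pairs), a
    slice, or an explicit index sequence.
    """
    if window is None or window == "all":
        return np.arange(n_pairs)
    if isinstance(window, str):
        if window.startswith("terminal:"):
            k = int(window.split(":", 1)[1])
            if not (1 <= k <= n_pairs):
                raise ValueError(f"terminal window size {k} out of range")
            return np.arange(n_pairs - k, n_pairs)
        raise ValueError(f"unknown window spec {window!r}")
    if isinstance(window, slice):
        return np.arange(n_pairs)[window]
    idx = np.asarray(sorted(set(int(i) for i in window)), dtype=np.intp)
    if idx.size and (idx[0] < 0 or idx[-1] >= n_pairs):
        raise ValueError("window indices out of range")
    return idx


def average_rise(
    traj: TrajectorySet,
    pairing: BasePairing,
    window: Sequence[int] | slice | str | None = None,
    keep_per_step: bool = False,
) -> RiseSeries:
    """Mean base-pair rise per frame over a window of consecutive pairs.

    Per frame, the rise of each step inside the window is the distance
    between consecutive base-pair centers; the series holds the mean
    over those steps.  Rotation- and translation-invariant.
    """
    win = _resolve_window(len(pairing), window)
    if win.size < 2:
        raise ValueError("rise needs a window of at least 2 base pairs")
    idx = _c1_indices(topology=traj.topology, pairing=pairing)[win]
    centers = 0.5 * (traj.coords[:, idx[:, 0], :] + traj.coords[:, idx[:, 1], :])
    steps = np.linalg.norm(np.diff(centers, axis=1), axis=2)  # (n_frames, n_steps)
    return RiseSeries(
        times=traj.times.copy(),
        mean_rise=steps.mean(axis=1),
        per_step_rise=steps if keep_per_step else None,
    )


def broken_bp_count(
    traj: TrajectorySet,
    pairing: BasePairing,
    cutoff: float = DEFAULT_BROKEN_CUTOFF,
    window: Sequence[int] | slice | str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame count of broken pairs in a window.

    A pair is broken in a frame iff its Watson–Crick donor–acceptor
    proxy distance (N1–N3) exceeds ``cutoff``.  Returns (times, counts).
    """
    win = _resolve_window(len(pairing), window)
    if win.size < 1:
        raise ValueError("window contains no base pairs")
    proxy = np.array(
        [
            _wc_proxy_indices(traj.topology, *pairing.pairs[int(i)])
            for i in win
        ],
        dtype=np.intp,
    )
    d = np.linalg.norm(
        traj.coords[:, proxy[:, 0], :] - traj.coords[:, proxy[:, 1], :], axis=2
    )
    return traj.times.copy(), (d > cutoff).sum(axis=1).astype(int)
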