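"""Synthetic structures and trajectories with known ground truth.

The generators emulate the statistical structure of membrane-anchored
DNA systems so that each analysis stage can be validated end to end:

* :func:`gen_bdna` — an idealized B-form duplex whose base-pair centers
  are spaced by exactly the requested rise (default 3.32 Å) with a fixed
  twist per step (default 36°);
* :func:`gen_bilayer` — two lipid leaflets represented by one glycerol
  C2 atom per lipid, noisy planar sheets with an optional thinned disk;
* :func:`gen_water_slab` — water oxygens partitioned exactly inside and
  outside a slab around the membrane midplane;
* :func:`gen_anchored_trajectory` — the duplex translated rigidly frame
  by frame so that the center of mass of its anchored segment follows an
  exact discrete Ornstein–Uhlenbeck process with a chosen stationary SD;
* :func:`gen_smd_record` — constant-velocity pull records whose work
  integral is known in closed form.

Nucleotides are coarse proxy residues (P, C1′ and a Watson–Crick
donor/acceptor nitrogen per base) rather than all-atom: the downstream
metrics only need base-pair centers, C1′ positions and one
donor–acceptor pair, and real all-atom inputs reach the same code paths
through atom selections.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import special

from dnanchor.io_model import (
    Atom,
    ConstructSpec,
    Selection,
    Topology,
    TrajectorySet,
    belt_bp_range,
)
from dnanchor.smd import SMDRecord

__all__ = [
    "BDnaParams",
    "BilayerParams",
    "ThinningSpec",
    "OUParams",
    "gen_bdna",
    "default_pairing",
    "fray_terminal_bps",
    "gen_bilayer",
    "gen_water_slab",
    "ou_series",
    "gen_anchored_trajectory",
    "gen_smd_record",
    "ConstantForce",
    "LinearForce",
    "GaussianForce",
]

# Internal helix geometry of the proxy duplex (Å).  The C1' radius sets
# the canonical ~10.4 Å C1'-C1' separation across a pair; the proxy
# Watson-Crick nitrogens sit 1.4 Å either side of the pair center so an
# intact pair has a 2.8 Å donor-acceptor distance (typical heavy-atom
# hydrogen-bond length).
_C1_RADIUS = 5.2
_WC_RADIUS = 1.4
_INTACT_WC_DISTANCE = 2 * _WC_RADIUS


@dataclass(frozen=True)
class BDnaParams:
    """Fiber-model B-DNA step parameters."""

    n_bp: int = 30
    rise: float = 3.32  # Å per step
    twist: float = 36.0  # degrees per step
    radius: float = 9.4  # Å, backbone (phosphate) reference radius

    def __post_init__(self) -> None:
        if self.n_bp < 2:
            raise ValueError("n_bp must be >= 2")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (0 < self.twist <= 60):
            raise ValueError("twist must lie in (0, 60] degrees")


@dataclass(frozen=True)
class ThinningSpec:
    """Local membrane thinning: inside a lateral disk of ``radius`` around
    ``center_xy``, both leaflet planes are moved inward by ``delta_z``."""

    center_xy: tuple[float, float]
    radius: float
    delta_z: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("thinning radius must be positive")


@dataclass(frozen=True)
class BilayerParams:
    """Two planar leaflets of lipid C2 atoms at z = ±leaflet_z."""

    n_per_leaflet: int = 128
    leaflet_z: float = 19.0  # Å, C2 plane position
    z_noise_sd: float = 1.0  # Å
    box_xy: float = 80.0  # Å
    thinning: ThinningSpec | None = None

    def __post_init__(self) -> None:
        if self.n_per_leaflet < 1:
            raise ValueError("n_per_leaflet must be >= 1")
        if self.leaflet_z <= 0:
            raise ValueError("leaflet_z must be positive")
        if self.z_noise_sd < 0:
            raise ValueError("z_noise_sd must be non-negative")


@dataclass(frozen=True)
class OUParams:
    """Discrete Ornstein–Uhlenbeck model for the anchored-segment CoM Z.

    The stationary distribution is N(mean_z, stationary_sd²); successive
    frames satisfy the exact update
    Z(t+dt) = mean_z + (Z(t) - mean_z)·e^(-dt/τ) + N(0, σ²(1 - e^(-2dt/τ))).
    The default relaxation time of 1 ns reflects the nanosecond-scale
    decorrelation expected for the CoM of a lipid-anchored segment.
    """

    stationary_sd: float = 1.05  # Å
    relaxation_time: float = 1.0  # ns
    mean_z: float = 0.0  # Å, relative to the bilayer midplane
    dt: float = 0.02  # ns per frame
    n_frames: int = 50_000  # 1 µs at 20 ps/frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stationary_sd <= 0:
            raise ValueError("stationary_sd must be positive")
        if self.relaxation_time <= 0:
            raise ValueError("relaxation_time must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


# ---------------------------------------------------------------------------
# Idealized B-form duplex
# ---------------------------------------------------------------------------


def gen_bdna(params: BDnaParams) -> tuple[Topology, np.ndarray]:
    """Build an idealized B-form duplex of proxy nucleotides.

    Strand A (chain ``A``, residues 1..n_bp, all ``DA``) and strand B
    (chain ``B``, residues 1..n_bp, all ``DT``) are antiparallel: base
    pair *i* joins A:*i* with B:*n_bp+1-i*.  Each nucleotide carries
    three named atoms — ``P`` (backbone), ``C1'`` and its Watson–Crick
    proxy nitrogen (``N1`` on the purine strand, ``N3`` on the
    pyrimidine strand).  Consecutive base-pair centers (C1'–C1'
    midpoints) are separated by exactly ``params.rise`` along z, and
    each step is rotated by ``params.twist`` degrees.
    """
    n = params.n_bp
    twist_rad = math.radians(params.twist)
    atoms: list[Atom] = []
    coords: list[list[float]] = []

    def add_atom(name: str, element: str, resname: str, resid: int, chain: str, xyz) -> None:
        atoms.append(Atom(len(atoms), name, element, resname, resid, chain))
        coords.append(list(xyz))

    # strand A: residue i+1 sits at bp step i
    for i in range(n):
        theta = i * twist_rad
        c, s = math.cos(theta), math.sin(theta)
        z = i * params.rise
        resid = i + 1
        add_atom("P", "P", "DA", resid, "A", (params.radius * c, params.radius * s, z))
        add_atom("C1'", "C", "DA", resid, "A", (_C1_RADIUS * c, _C1_RADIUS * s, z))
        add_atom("N1", "N", "DA", resid, "A", (_WC_RADIUS * c, _WC_RADIUS * s, z))
    # strand B: residue r pairs with bp step i = n - r (antiparallel)
    for r in range(1, n + 1):
        i = n - r
        theta = i * twist_rad
        c, s = math.cos(theta), math.sin(theta)
        z = i * params.rise
        add_atom("P", "P", "DT", r, "B", (-params.radius * c, -params.radius * s, z))
        add_atom("C1'", "C", "DT", r, "B", (-_C1_RADIUS * c, -_C1_RADIUS * s, z))
        add_atom("N3", "N", "DT", r, "B", (-_WC_RADIUS * c, -_WC_RADIUS * s, z))
    return Topology(atoms), np.asarray(coords, dtype=float)


def default_pairing(n_bp: int):
    """Watson–Crick pairing of a :func:`gen_bdna` duplex as
    (chain A residue i, chain B residue n_bp+1-i) tuples, 5'→3' on A."""
    from dnanchor.dna_structure import BasePairing

    return BasePairing.from_duplex(n_bp)


def fray_terminal_bps(
    topology: Topology,
    coords: np.ndarray,
    k: int,
    displacement: float,
    pairing=None,
    end: str = "last",
) -> np.ndarray:
    """Open ``k`` terminal base pairs by ``displacement`` Å.

    The chain-B residue of each affected pair is translated along its
    pair-opening direction (from the A-strand donor nitrogen toward the
    B-strand acceptor), so the donor–acceptor distance becomes exactly
    (intact distance + displacement) — strictly monotone in the
    displacement.  ``end`` selects which terminus frays (``"last"`` =
    high bp numbers, ``"first"`` = bp 1..k).  Remaining pairs are
    untouched.
    """
    from dnanchor.dna_structure import BasePairing, _wc_proxy_indices

    if pairing is None:
        n_bp = int(np.sum((topology.chains == "A") & (topology.names == "C1'")))
        pairing = BasePairing.from_duplex(n_bp)
    n_pairs = len(pairing.pairs)
    if not (1 <= k <= n_pairs):
        raise ValueError(f"k must satisfy 1 <= k <= {n_pairs}, got {k}")
    if end not in ("first", "last"):
        raise ValueError("end must be 'first' or 'last'")
    affected = pairing.pairs[:k] if end == "first" else pairing.pairs[-k:]
    out = np.array(coords, dtype=float, copy=True)
    chains, resids = topology.chains, topology.resids
    for res1, res2 in affected:
        i_don, i_acc = _wc_proxy_indices(topology, res1, res2)
        v = out[i_acc] - out[i_don]
        norm = float(np.linalg.norm(v))
        if norm == 0:
            raise ValueError(f"degenerate pair geometry for {res1} / {res2}")
        shift = displacement * v / norm
        res_mask = (chains == res2[0]) & (resids == res2[1])
        out[res_mask] += shift
    return out


# ---------------------------------------------------------------------------
# Bilayer and water
# ---------------------------------------------------------------------------


def _bilayer_base(params: BilayerParams, rng: np.random.Generator) -> tuple[Topology, np.ndarray]:
    """Noise-free bilayer: C2 atoms on their leaflet planes (thinning applied)."""
    n = params.n_per_leaflet
    atoms: list[Atom] = []
    coords = np.empty((2 * n, 3), dtype=float)
    xy = rng.uniform(0.0, params.box_xy, size=(2 * n, 2))
    for leaflet, (chain, sign) in enumerate([("U", 1.0), ("L", -1.0)]):
        for j in range(n):
            idx = leaflet * n + j
            atoms.append(Atom(idx, "C2", "C", "POPC", j + 1, chain))
            base_z = sign * params.leaflet_z
            if params.thinning is not None:
                dx = xy[idx] - np.asarray(params.thinning.center_xy)
                # minimum image in the periodic xy plane
                dx -= params.box_xy * np.round(dx / params.box_xy)
                if float(np.hypot(*dx)) <= params.thinning.radius:
                    base_z = sign * (params.leaflet_z - params.thinning.delta_z)
            coords[idx] = (xy[idx, 0], xy[idx, 1], base_z)
    return Topology(atoms), coords


def gen_bilayer(params: BilayerParams, seed: int = 0) -> tuple[Topology, np.ndarray]:
    """Generate one frame of a noisy planar C2-atom bilayer.

    Each leaflet holds ``n_per_leaflet`` C2 atoms at z = ±leaflet_z plus
    independent N(0, z_noise_sd²) displacements; inside the optional
    thinning disk the planes are moved inward by ``delta_z`` first.
    """
    rng = np.random.default_rng(seed)
    top, coords = _bilayer_base(params, rng)
    coords = coords.copy()
    coords[:, 2] += params.z_noise_sd * rng.standard_normal(coords.shape[0])
    return top, coords


def gen_water_slab(
    n_inside: int,
    n_outside: int,
    half_width: float,
    box: Sequence[float],
    seed: int = 0,
    margin: float = 0.5,
) -> tuple[Topology, np.ndarray]:
    """Water oxygens placed exactly inside/outside a slab |z| < half_width.

    ``n_inside`` oxygens satisfy |z| < half_width - margin and
    ``n_outside`` satisfy half_width + margin < |z| < box_z/2, so a
    downstream slab count at the same half-width returns ``n_inside``
    exactly (the margin avoids boundary ties).
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    lx, ly, lz = box
    if lz / 2 <= half_width + margin:
        raise ValueError("box z too small for the requested slab + margin")
    rng = np.random.default_rng(seed)
    n = n_inside + n_outside
    atoms = [Atom(i, "O", "O", "HOH", i + 1, "W") for i in range(n)]
    coords = np.empty((n, 3), dtype=float)
    coords[:, 0] = rng.uniform(0.0, lx, size=n)
    coords[:, 1] = rng.uniform(0.0, ly, size=n)
    coords[:n_inside, 2] = rng.uniform(-(half_width - margin), half_width - margin, size=n_inside)
    out_z = rng.uniform(half_width + margin, lz / 2, size=n_outside)
    signs = np.where(np.arange(n_outside) % 2 == 0, 1.0, -1.0)
    coords[n_inside:, 2] = signs * out_z
    return Topology(atoms), coords


# ---------------------------------------------------------------------------
# Anchored trajectory (Ornstein–Uhlenbeck placement model)
# ---------------------------------------------------------------------------


def ou_series(params: OUParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample the exact discrete OU process defined by ``params``.

    Z(0) is drawn from the stationary distribution, so no burn-in bias
    exists; the per-step update uses the exact conditional law of the
    continuous process, making the series stationary at every lag.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    phi = math.exp(-params.dt / params.relaxation_time)
    step_sd = params.stationary_sd * math.sqrt(1.0 - phi * phi)
    z = np.empty(params.n_frames)
    z[0] = params.mean_z + params.stationary_sd * rng.standard_normal()
    eps = step_sd * rng.standard_normal(params.n_frames - 1)
    for i in range(1, params.n_frames):
        z[i] = params.mean_z + phi * (z[i - 1] - params.mean_z) + eps[i - 1]
    return z


def gen_anchored_trajectory(
    duplex: tuple[Topology, np.ndarray],
    bilayer: BilayerParams,
    ou: OUParams,
    belt: Selection | None = None,
    water: tuple[Topology, np.ndarray] | None = None,
    box_z: float | None = None,
) -> TrajectorySet:
    """Combine a duplex with a bilayer into a seeded synthetic trajectory.

    Per frame the duplex is translated rigidly along z so that the
    mass-weighted CoM Z of ``belt`` (default: the whole duplex) follows
    the exact discrete OU process of ``ou``; bilayer C2 atoms receive
    fresh z-noise each frame; optional water coordinates are static.
    Bit-reproducible from ``ou.seed``.
    """
    dup_top, dup_coords = duplex
    rng = np.random.default_rng(ou.seed)
    z_series = ou_series(ou, rng)
    bil_top, bil_base = _bilayer_base(bilayer, rng)

    top = dup_top.concat(bil_top)
    coords_blocks = [dup_coords, bil_base]
    if water is not None:
        wat_top, wat_coords = water
        top = top.concat(wat_top)
        coords_blocks.append(wat_coords)

    n_dup = dup_top.n_atoms
    n_bil = bil_top.n_atoms
    n_frames = ou.n_frames

    belt_idx = belt.array if belt is not None else np.arange(n_dup)
    masses = dup_top.masses[belt_idx]
    belt_com_z0 = float(np.average(dup_coords[belt_idx, 2], weights=masses))
    shifts = z_series - belt_com_z0  # z translation per frame

    n_atoms = top.n_atoms
    coords = np.empty((n_frames, n_atoms, 3))
    static = np.concatenate(coords_blocks, axis=0)
    coords[:] = static[None, :, :]
    coords[:, :n_dup, 2] += shifts[:, None]
    noise = bilayer.z_noise_sd * rng.standard_normal((n_frames, n_bil))
    coords[:, n_dup : n_dup + n_bil, 2] += noise

    if box_z is None:
        box_z = 2.0 * (bilayer.leaflet_z + 40.0)
    times = ou.dt * np.arange(n_frames)
    boxes = np.tile([bilayer.box_xy, bilayer.box_xy, box_z], (n_frames, 1))
    return TrajectorySet(top, times, boxes, coords)


# ---------------------------------------------------------------------------
# Steered-MD records with analytic work
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantForce:
    """F(z) = f0 (pN); work over [z0, z1] is f0·(z1-z0)."""

    f0: float

    def __call__(self, z):
        return np.full_like(np.asarray(z, dtype=float), self.f0)

    def work(self, z0: float, z1: float) -> float:
        return self.f0 * (z1 - z0)


@dataclass(frozen=True)
class LinearForce:
    """F(z) = slope·z + intercept; work is the exact quadratic integral."""

    slope: float
    intercept: float = 0.0

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        return self.slope * z + self.intercept

    def work(self, z0: float, z1: float) -> float:
        return 0.5 * self.slope * (z1**2 - z0**2) + self.intercept * (z1 - z0)


@dataclass(frozen=True)
class GaussianForce:
    """Bell-shaped resistance F(z) = A·exp(-(z-c)²/2w²); work via erf."""

    amplitude: float
    center: float
    width: float

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        return self.amplitude * np.exp(-((z - self.center) ** 2) / (2 * self.width**2))

    def work(self, z0: float, z1: float) -> float:
        s = self.width * math.sqrt(2.0)
        return float(
            self.amplitude
            * self.width
            * math.sqrt(math.pi / 2.0)
            * (special.erf((z1 - self.center) / s) - special.erf((z0 - self.center) / s))
        )


def gen_smd_record(
    force_profile: Callable[[np.ndarray], np.ndarray],
    z_start: float,
    z_end: float,
    velocity: float = 0.5,
    dt: float = 0.02,
) -> SMDRecord:
    """Constant-velocity pull record: z(t) = z_start + velocity·t.

    The sampled force is ``force_profile(z)`` evaluated on an exact
    uniform grid that includes both endpoints, so the trapezoidal work
    can be compared against a closed-form ∫F dz for the profiles above.
    """
    if z_end <= z_start:
        raise ValueError("z_end must exceed z_start")
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    duration = (z_end - z_start) / velocity
    n = max(2, int(round(duration / dt)) + 1)
    times = np.linspace(0.0, duration, n)
    z = z_start + velocity * times
    force = np.asarray(force_profile(z), dtype=float)
    return SMDRecord(times=times, z=z, force=force)
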