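"""Internal data model, structure/trajectory I/O and atom selections.

Units are Å for lengths and ns for times throughout the package.  Atom
indices are 0-based internally; residue numbers follow the 1-based PDB
convention at the file interface.

File I/O is delegated to MDAnalysis; this module only converts between
MDAnalysis universes and the package's plain dataclass containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "TrajectorySet",
    "Selection",
    "ConstructSpec",
    "StructureParseError",
    "TrajectoryReadError",
    "SelectionError",
    "SelectionSyntaxError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
    "count_ppt_pairs",
    "belt_bp_range",
    "belt_resid_range",
]

# Standard atomic masses (u); unknown elements fall back to 1.0.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}


class StructureParseError(ValueError):
    """A structure file could not be parsed."""


class TrajectoryReadError(ValueError):
    """A trajectory file could not be read completely."""


class SelectionError(ValueError):
    """A selection query matched no atoms or referenced missing atoms."""


class SelectionSyntaxError(ValueError):
    """A selection query does not follow the documented grammar."""


@dataclass(frozen=True)
class Atom:
    """One atom: 0-based index plus PDB-style metadata."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str


@dataclass
class Topology:
    """Atom metadata shared by all frames of a trajectory.

    Invariants: atom indices are unique and contiguous from 0, and a
    residue index maps to exactly one residue name within a chain.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("atom indices must be unique and contiguous from 0")
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_index)
            if seen.setdefault(key, a.residue_name) != a.residue_name:
                raise ValueError(
                    f"residue {a.residue_index} in chain {a.chain_id!r} has "
                    f"conflicting names {seen[key]!r} and {a.residue_name!r}"
                )
        if self.bonds is not None:
            n = len(self.atoms)
            for i, j in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"bond ({i}, {j}) references missing atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # Cached per-field numpy views used by the selection engine and the
    # vectorized analysis code.
    def _arrays(self) -> dict[str, np.ndarray]:
        cache = self.__dict__.get("_array_cache")
        if cache is None:
            cache = {
                "name": np.array([a.name for a in self.atoms]),
                "element": np.array([a.element for a in self.atoms]),
                "resname": np.array([a.residue_name for a in self.atoms]),
                "resid": np.array([a.residue_index for a in self.atoms]),
                "chain": np.array([a.chain_id for a in self.atoms]),
            }
            self.__dict__["_array_cache"] = cache
        return cache

    @property
    def names(self) -> np.ndarray:
        return self._arrays()["name"]

    @property
    def elements(self) -> np.ndarray:
        return self._arrays()["element"]

    @property
    def resnames(self) -> np.ndarray:
        return self._arrays()["resname"]

    @property
    def resids(self) -> np.ndarray:
        return self._arrays()["resid"]

    @property
    def chains(self) -> np.ndarray:
        return self._arrays()["chain"]

    @property
    def masses(self) -> np.ndarray:
        cache = self.__dict__.get("_mass_cache")
        if cache is None:
            cache = np.array(
                [ATOMIC_MASSES.get(a.element.upper(), 1.0) for a in self.atoms]
            )
            self.__dict__["_mass_cache"] = cache
        return cache

    def concat(self, other: "Topology") -> "Topology":
        """Concatenate two topologies, reindexing the second block."""
        off = self.n_atoms
        atoms = list(self.atoms) + [
            Atom(off + a.index, a.name, a.element, a.residue_name, a.residue_index, a.chain_id)
            for a in other.atoms
        ]
        return Topology(atoms)


@dataclass
class TrajectorySet:
    """Topology plus frames: times (ns), boxes (Å) and coordinates (Å).

    ``coords`` has shape (n_frames, n_atoms, 3); ``boxes`` holds the three
    orthorhombic box lengths per frame.
    """

    topology: Topology
    times: np.ndarray
    boxes: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms per frame but the "
                f"topology has {self.topology.n_atoms}"
            )
        n = self.coords.shape[0]
        if self.times.shape != (n,):
            raise ValueError("times must have one entry per frame")
        if self.boxes.shape != (n, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


@dataclass(frozen=True)
class Selection:
    """A labelled, sorted, non-empty set of atom indices."""

    label: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise SelectionError(f"selection {self.label!r} is empty")
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        object.__setattr__(self, "indices", idx)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.indices)


VALID_BELT_POSITIONS = ("terminal", "central", "none")
VALID_ALKYL = ("ethyl", "butyl", "hexyl", "none")
VALID_ANCHORS = ("alkyl-PPT", "cholesterol", "porphyrin", "none")


@dataclass(frozen=True)
class ConstructSpec:
    """Design of one duplex construct.

    ``ppt_pairs`` counts base pairs carrying a pair of alkylated
    phosphorothioate (PPT) groups; six contiguous pairs form a "belt"
    placed either terminally or centrally on the duplex.
    """

    n_bp: int
    belt_position: str = "none"
    ppt_pairs: int = 0
    alkyl: str = "none"
    anchor: str = "none"

    def __post_init__(self) -> None:
        if self.n_bp < 2:
            raise ValueError("n_bp must be at least 2")
        if self.belt_position not in VALID_BELT_POSITIONS:
            raise ValueError(f"belt_position must be one of {VALID_BELT_POSITIONS}")
        if self.alkyl not in VALID_ALKYL:
            raise ValueError(f"alkyl must be one of {VALID_ALKYL}")
        if self.anchor not in VALID_ANCHORS:
            raise ValueError(f"anchor must be one of {VALID_ANCHORS}")
        if not (0 <= self.ppt_pairs <= self.n_bp):
            raise ValueError("ppt_pairs must satisfy 0 <= ppt_pairs <= n_bp")
        if (self.belt_position == "none") != (self.ppt_pairs == 0):
            raise ValueError("belt_position is 'none' if and only if ppt_pairs is 0")


def count_ppt_pairs(spec: ConstructSpec) -> int:
    """Number of PPT-modified base pairs in the construct's belt."""
    return spec.ppt_pairs


def belt_bp_range(spec: ConstructSpec) -> range | None:
    """1-based base-pair numbers covered by the belt, or None.

    Terminal belts start at bp 1; central belts occupy
    bp (n_bp - ppt)/2 + 1 .. (n_bp + ppt)/2 (integer division), which is
    symmetric about the duplex midpoint whenever n_bp and ppt_pairs have
    the same parity.
    """
    if spec.ppt_pairs == 0:
        return None
    if spec.belt_position == "terminal":
        return range(1, spec.ppt_pairs + 1)
    start = (spec.n_bp - spec.ppt_pairs) // 2 + 1
    return range(start, start + spec.ppt_pairs)


def belt_resid_range(spec: ConstructSpec) -> range | None:
    """Alias for :func:`belt_bp_range`: on the idealized duplexes built by
    :mod:`dnanchor.synthetic` the belt's bp numbers equal the residue
    numbers on *both* strands (the antiparallel partner of bp *i* is
    residue n_bp + 1 - i, and the belt window maps onto itself)."""
    return belt_bp_range(spec)


# ---------------------------------------------------------------------------
# Structure / trajectory I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def _prescan_pdb(path: Path) -> int:
    """Validate ATOM/HETATM records line by line; return the atom count.

    Raises :class:`StructureParseError` naming the offending line for
    malformed coordinates or duplicate atom serial numbers.
    """
    n_atoms = 0
    serials: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path}: line {lineno}: ATOM record shorter than 54 columns"
                )
            serial = line[6:11].strip()
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise StructureParseError(
                    f"{path}: line {lineno}: malformed coordinate fields"
                ) from None
            if serial in serials:
                raise StructureParseError(
                    f"{path}: line {lineno}: duplicate atom serial {serial}"
                )
            serials.add(serial)
            n_atoms += 1
    if n_atoms == 0:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    return n_atoms


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _topology_from_universe(u) -> Topology:
    ag = u.atoms
    n = len(ag)
    names = ag.names
    resnames = ag.resnames
    resids = ag.resids
    if hasattr(ag, "chainIDs"):
        chains = ag.chainIDs
    elif hasattr(ag, "segids"):
        chains = ag.segids
    else:
        chains = [""] * n
    if hasattr(ag, "elements"):
        elements = [e if e else _guess_element(nm) for e, nm in zip(ag.elements, names)]
    else:
        elements = [_guess_element(nm) for nm in names]
    atoms = [
        Atom(i, str(names[i]), str(elements[i]), str(resnames[i]), int(resids[i]), str(chains[i]).strip())
        for i in range(n)
    ]
    return Topology(atoms)


def read_structure(path: str | Path, format: str = "pdb") -> tuple[Topology, np.ndarray]:
    """Read a structure file into a Topology and one coordinate frame (Å)."""
    import MDAnalysis as mda

    path = Path(path)
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}; only 'pdb'")
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # pragma: no cover - prescan catches most
            raise StructureParseError(f"{path}: {exc}") from exc
        top = _topology_from_universe(u)
        coords = u.atoms.positions.astype(float).copy()
    return top, coords


def write_structure(
    topology: Topology,
    coords: np.ndarray,
    path: str | Path,
    box: Sequence[float] | None = None,
) -> None:
    """Write a Topology plus one frame of coordinates as PDB."""
    u = _universe_from_topology(topology, box=box)
    u.atoms.positions = np.asarray(coords, dtype=np.float32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _universe_from_topology(topology: Topology, box: Sequence[float] | None = None):
    import MDAnalysis as mda

    n = topology.n_atoms
    # one MDAnalysis "residue" per (chain, resid) run
    res_keys: list[tuple[str, int]] = []
    atom_resindex = np.empty(n, dtype=int)
    for a in topology.atoms:
        key = (a.chain_id, a.residue_index)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[a.index] = len(res_keys) - 1
    seg_ids: list[str] = []
    residue_segindex = []
    for chain, _ in res_keys:
        if not seg_ids or seg_ids[-1] != chain:
            seg_ids.append(chain)
        residue_segindex.append(len(seg_ids) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n,
            n_residues=len(res_keys),
            n_segments=len(seg_ids),
            atom_resindex=atom_resindex,
            residue_segindex=np.asarray(residue_segindex),
            trajectory=True,
        )
        u.add_TopologyAttr("names", topology.names)
        u.add_TopologyAttr("elements", topology.elements)
        u.add_TopologyAttr("chainIDs", topology.chains)
        resname_by_key = {}
        for a in topology.atoms:
            resname_by_key[(a.chain_id, a.residue_index)] = a.residue_name
        u.add_TopologyAttr("resnames", [resname_by_key[k] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("segids", seg_ids)
        if box is not None:
            u.dimensions = [box[0], box[1], box[2], 90.0, 90.0, 90.0]
    return u


def read_trajectory(
    topology: Topology,
    path: str | Path,
    format: str | None = None,
    dt_ns: float | None = None,
    t0_ns: float = 0.0,
) -> TrajectorySet:
    """Read a DCD/XTC trajectory against a known topology.

    Frame times are taken from the file (ps, converted to ns) when present;
    ``dt_ns`` overrides them (DCD headers often carry a nominal timestep
    only).  Raises :class:`TrajectoryReadError` on an atom-count mismatch
    or a truncated file (the error reports the number of frames read).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("dcd", "xtc"):
        raise ValueError(f"unsupported trajectory format {fmt!r}; use dcd or xtc")
    u = _universe_from_topology(topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u.load_new(str(path), format=fmt)
        except (ValueError, IOError, EOFError) as exc:
            raise TrajectoryReadError(f"{path}: {exc}") from exc
        if u.trajectory.n_atoms != topology.n_atoms:
            raise TrajectoryReadError(
                f"{path}: trajectory has {u.trajectory.n_atoms} atoms but the "
                f"topology has {topology.n_atoms}"
            )
        times, boxes, frames = [], [], []
        try:
            for ts in u.trajectory:
                times.append(float(ts.time))
                dims = ts.dimensions
                boxes.append([0.0, 0.0, 0.0] if dims is None else list(dims[:3]))
                frames.append(ts.positions.astype(float).copy())
        except (IOError, EOFError, ValueError) as exc:
            raise TrajectoryReadError(
                f"{path}: truncated after reading {len(frames)} frames: {exc}"
            ) from exc
    if fmt == "dcd":
        # the header stores the frame count written (NSET); fewer frames on
        # disk than promised means the file was truncated mid-stream
        with open(path, "rb") as fh:
            header = fh.read(12)
        if len(header) == 12 and header[4:8] == b"CORD":
            nset = int.from_bytes(header[8:12], "little", signed=True)
            if nset > 0 and len(frames) < nset:
                raise TrajectoryReadError(
                    f"{path}: truncated file: header promises {nset} frames "
                    f"but only {len(frames)} could be read"
                )
    times_ns = np.asarray(times) / 1000.0  # MDAnalysis times are ps
    if dt_ns is not None or len(times_ns) > 1 and not np.all(np.diff(times_ns) > 0):
        dt = dt_ns if dt_ns is not None else 0.02
        times_ns = t0_ns + dt * np.arange(len(frames))
    return TrajectorySet(topology, times_ns, np.asarray(boxes), np.asarray(frames))


def write_trajectory(traj: TrajectorySet, path: str | Path, format: str | None = None) -> None:
    """Write a TrajectorySet as DCD or XTC (format from the extension)."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("dcd", "xtc"):
        raise ValueError(f"unsupported trajectory format {fmt!r}; use dcd or xtc")
    u = _universe_from_topology(traj.topology)
    dt_ps = 1.0
    if traj.n_frames > 1:
        dt_ps = float(traj.times[1] - traj.times[0]) * 1000.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, format=fmt.upper(), dt=dt_ps) as w:
            for i in range(traj.n_frames):
                ts = u.trajectory.ts
                u.atoms.positions = traj.coords[i].astype(np.float32)
                ts.dimensions = [*traj.boxes[i], 90.0, 90.0, 90.0]
                ts.time = float(traj.times[i]) * 1000.0
                ts.frame = i
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
# expr   := term ("or" term)*
# term   := factor ("and" factor)*
# factor := "not" factor | "(" expr ")" | clause
# clause := ("name" | "resname" | "resid" | "chain" | "element") value+
#
# Values for "resid" may be single numbers or inclusive ranges "i:j".
# Multiple values after one keyword are OR-ed ("name N1 N3").

_KEYWORDS = ("name", "resname", "resid", "chain", "element")
_OPERATORS = ("and", "or", "not", "(", ")")


def _tokenize(query: str) -> list[str]:
    out: list[str] = []
    for chunk in query.replace("(", " ( ").replace(")", " ) ").split():
        out.append(chunk)
    return out


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of query")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionSyntaxError("missing closing parenthesis")
            return mask
        return self.clause()

    def clause(self) -> np.ndarray:
        keyword = self.take()
        if keyword not in _KEYWORDS:
            raise SelectionSyntaxError(
                f"expected one of {_KEYWORDS}, got {keyword!r}"
            )
        values: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS + _OPERATORS:
            values.append(self.take())
        if not values:
            raise SelectionSyntaxError(f"keyword {keyword!r} needs at least one value")
        arrays = self.top._arrays()
        if keyword == "resid":
            resids = arrays["resid"]
            mask = np.zeros(self.top.n_atoms, dtype=bool)
            for v in values:
                try:
                    if ":" in v:
                        lo, hi = (int(x) for x in v.split(":", 1))
                        mask |= (resids >= lo) & (resids <= hi)
                    else:
                        mask |= resids == int(v)
                except ValueError:
                    raise SelectionSyntaxError(
                        f"resid value {v!r} is not an integer or i:j range"
                    ) from None
            return mask
        col = arrays[keyword]
        return np.isin(col, values)


def select(topology: Topology, query: str) -> Selection:
    """Resolve a selection query to a sorted, non-empty atom index set.

    The grammar is a small documented subset: ``name``, ``resname``,
    ``resid`` (single or ``i:j`` range), ``chain`` and ``element``
    clauses combined with ``and``/``or``/``not`` and parentheses.
    Deterministic: the same query on the same topology always yields the
    identical index list.
    """
    tokens = _tokenize(query)
    if not tokens:
        raise SelectionSyntaxError("empty query")
    mask = _Parser(tokens, topology).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"query {query!r} matched no atoms")
    return Selection(label=query, indices=tuple(int(i) for i in idx))
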