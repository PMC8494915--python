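"""Trajectory features: side-chain distance vectors, RMSF/RMSD, contacts.

The central object is the :class:`FeatureMatrix` — one row per residue
pair, one column per sampled time step, holding the distance between the
side-chain heavy-atom centers of mass of the two residues.  These per-pair
distance time series are the input vectors of the autoencoder.  The module
also computes the standard trajectory statistics used to characterise the
apo/holo systems: per-atom RMSF, per-frame RMSD, and residue-residue
contact counts under a distance cutoff, aggregated by EC/TM/IC region
pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .regions import RegionMap

__all__ = [
    "TrajectoryFrames",
    "FeatureMatrix",
    "ContactTable",
    "load_trajectory",
    "time_grid",
    "sidechain_center",
    "sidechain_centers",
    "pair_distance_series",
    "build_feature_matrix",
    "compute_rmsf",
    "compute_rmsd",
    "count_contacts",
    "select_differential_region_pairs",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

# standard atomic masses (u) for the elements that occur in protein heavy
# atoms plus hydrogen; used when a trajectory provides element symbols
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


@dataclass
class TrajectoryFrames:
    """Fixed-roster trajectory: coordinates in Å, times in ns.

    ``atoms`` has one row per atom with columns ``resid``, ``resname``,
    ``name``, ``element``, ``mass`` and ``molecule`` (``"receptor"`` or
    ``"ligand"``).
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    times: np.ndarray  # (n_frames,), ns
    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("frame count of coords and times differ")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom roster size does not match coords")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residue_ids(self, molecule: str | None = None) -> list[int]:
        atoms = self.atoms
        if molecule is not None:
            atoms = atoms[atoms["molecule"] == molecule]
        return sorted(atoms["resid"].unique().tolist())

    def subsample(self, stride: int) -> "TrajectoryFrames":
        return TrajectoryFrames(self.coords[::stride], self.times[::stride], self.atoms)


@dataclass
class FeatureMatrix:
    """Residue-pair distance time series: rows = pairs (i<j), columns = steps."""

    pairs: list[tuple[int, int]]
    values: np.ndarray  # (n_pairs, n_steps), Å
    window: tuple[float, float, float]  # (t_start, t_end, stride) ns
    pair_molecules: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.pairs):
            raise ValueError("values shape does not match pair list")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def save(self, path: str) -> None:
        np.savez(
            path,
            values=self.values,
            pairs=np.asarray(self.pairs, dtype=int),
            window=np.asarray(self.window, dtype=float),
            pair_molecules=np.asarray(self.pair_molecules, dtype=object)
            if self.pair_molecules
            else np.empty((0, 2), dtype=object),
        )

    @classmethod
    def load(cls, path: str) -> "FeatureMatrix":
        with np.load(path, allow_pickle=True) as data:
            pairs = [tuple(int(x) for x in row) for row in data["pairs"]]
            mols = [tuple(row) for row in data["pair_molecules"]]
            return cls(
                pairs=pairs,
                values=data["values"],
                window=tuple(float(x) for x in data["window"]),
                pair_molecules=mols,
            )


@dataclass
class ContactTable:
    """Contact counts per (label_a, label_b) key, symmetric in the labels."""

    counts: pd.DataFrame  # columns: label_a, label_b, count
    cutoff: float
    mode: str
    total: int

    def lookup(self, a, b) -> int:
        key = tuple(sorted((a, b), key=str))
        df = self.counts
        hit = df[(df["label_a"] == key[0]) & (df["label_b"] == key[1])]
        return int(hit["count"].iloc[0]) if len(hit) else 0


# ---------------------------------------------------------------------------
# loading


def load_trajectory(
    topology: str,
    trajectory: str | None = None,
    stride: int = 1,
    ligand_chains: frozenset[str] = frozenset({"L"}),
    dt_ns: float | None = None,
) -> TrajectoryFrames:
    """Read a trajectory (multi-model PDB, or topology + XTC/TRR/DCD).

    Residues whose chain/segment identifier is in ``ligand_chains`` are
    tagged ``"ligand"``, everything else ``"receptor"``.  Coordinates are
    returned in Å (MDAnalysis' native unit); frame times in ns.  ``dt_ns``
    overrides the frame spacing — formats such as PDB carry no time
    information and would otherwise default to 1 ps per frame.
    """
    import MDAnalysis as mda

    if trajectory is None:
        u = mda.Universe(topology)
    else:
        u = mda.Universe(topology, trajectory)

    atoms = u.atoms
    names = atoms.names
    resids = atoms.resids
    resnames = atoms.resnames
    try:
        chains = atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        try:
            chains = atoms.segids
        except (AttributeError, mda.exceptions.NoDataError):
            chains = np.array([""] * len(atoms))

    try:
        elements = np.array([e.upper() for e in atoms.elements])
    except (AttributeError, mda.exceptions.NoDataError):
        elements = np.array([_element_from_name(n) for n in names])

    masses = np.array(
        [
            ELEMENT_MASSES.get(e, m)
            for e, m in zip(elements, _safe_masses(atoms, elements))
        ]
    )

    roster = pd.DataFrame(
        {
            "resid": resids.astype(int),
            "resname": resnames,
            "name": names,
            "element": elements,
            "mass": masses,
            "molecule": [
                "ligand" if str(c) in ligand_chains else "receptor" for c in chains
            ],
        }
    )

    coords, times = [], []
    for ts in u.trajectory[::stride]:
        if ts.positions.shape[0] != len(roster):
            raise ValueError(f"frame {ts.frame}: atom roster mismatch")
        coords.append(ts.positions.copy().astype(float))
        times.append(ts.time / 1000.0)  # MDAnalysis time is ps

    times = np.asarray(times)
    if dt_ns is not None:
        times = np.arange(len(coords), dtype=float) * float(dt_ns)
    elif len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(coords), dtype=float)
    return TrajectoryFrames(np.stack(coords), times, roster)


def _safe_masses(atoms, elements) -> np.ndarray:
    try:
        return np.asarray(atoms.masses, dtype=float)
    except Exception:
        return np.array([ELEMENT_MASSES.get(e, 12.011) for e in elements])


def _element_from_name(name: str) -> str:
    name = name.strip()
    for two in ("SE", "CL", "BR"):
        if name.upper().startswith(two):
            return two
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ---------------------------------------------------------------------------
# time grid and side-chain geometry


def time_grid(t_start: float, t_end: float, stride: float) -> np.ndarray:
    """Inclusive arithmetic grid ``t_start, t_start+stride, ... <= t_end``."""
    if stride <= 0:
        raise ValueError(f"stride must be > 0, got {stride}")
    if t_end < t_start:
        raise ValueError(f"t_end {t_end} < t_start {t_start}")
    n = int(np.floor((t_end - t_start) / stride + 1e-9)) + 1
    return t_start + stride * np.arange(n)


def sidechain_center(atoms: pd.DataFrame, coords: np.ndarray, mass_weighted: bool = True) -> np.ndarray:
    """Center of mass of a residue's side-chain heavy atoms.

    Backbone atoms (N, CA, C, O, OXT) and hydrogens are excluded; residues
    without heavy side-chain atoms (glycine) fall back to CA.
    """
    if len(atoms) == 0:
        raise ValueError("residue has no atoms")
    coords = np.asarray(coords, dtype=float)
    heavy = (atoms["element"].values != "H") & ~atoms["name"].isin(BACKBONE_NAMES).values
    if not heavy.any():
        ca = atoms["name"].values == "CA"
        if not ca.any():
            heavy = atoms["element"].values != "H"
            if not heavy.any():
                raise ValueError("residue has no non-hydrogen atom")
        else:
            heavy = ca
    sel = coords[heavy]
    if mass_weighted:
        w = atoms["mass"].values[heavy]
        return (sel * w[:, None]).sum(axis=0) / w.sum()
    return sel.mean(axis=0)


def sidechain_centers(
    frames: TrajectoryFrames, residues: list[int] | None = None, mass_weighted: bool = True
) -> tuple[np.ndarray, list[int]]:
    """Per-frame side-chain centers for a residue list: (n_frames, n_res, 3)."""
    if residues is None:
        residues = frames.residue_ids()
    atoms = frames.atoms
    centers = np.empty((frames.n_frames, len(residues), 3))
    for j, resid in enumerate(residues):
        mask = (atoms["resid"] == resid).values
        sub = atoms[mask]
        heavy = (sub["element"].values != "H") & ~sub["name"].isin(BACKBONE_NAMES).values
        if not heavy.any():
            ca = sub["name"].values == "CA"
            heavy = ca if ca.any() else (sub["element"].values != "H")
            if not heavy.any():
                raise ValueError(f"residue {resid} has no non-hydrogen atom")
        idx = np.flatnonzero(mask)[heavy]
        pts = frames.coords[:, idx, :]
        if mass_weighted:
            w = atoms["mass"].values[idx]
            centers[:, j, :] = (pts * w[None, :, None]).sum(axis=1) / w.sum()
        else:
            centers[:, j, :] = pts.mean(axis=1)
    return centers, list(residues)


def _grid_frame_indices(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if grid[0] < times[0] - 1e-9 or grid[-1] > times[-1] + 1e-9:
        raise ValueError(
            f"window [{grid[0]}, {grid[-1]}] ns exceeds trajectory span "
            f"[{times[0]}, {times[-1]}] ns"
        )
    pos = np.searchsorted(times, grid)
    pos = np.clip(pos, 0, len(times) - 1)
    left = np.clip(pos - 1, 0, len(times) - 1)
    use_left = np.abs(times[left] - grid) <= np.abs(times[pos] - grid)
    return np.where(use_left, left, pos)


def pair_distance_series(
    frames: TrajectoryFrames,
    pair: tuple[int, int],
    window: tuple[float, float, float],
    mass_weighted: bool = True,
) -> np.ndarray:
    """Side-chain center distance of one residue pair on the time grid."""
    i, j = pair
    if i >= j:
        raise ValueError(f"pairs require i < j, got ({i}, {j})")
    grid = time_grid(*window)
    idx = _grid_frame_indices(frames.times, grid)
    centers, _ = sidechain_centers(frames, [i, j], mass_weighted)
    diff = centers[idx, 0, :] - centers[idx, 1, :]
    return np.linalg.norm(diff, axis=1)


def build_feature_matrix(
    frames: TrajectoryFrames,
    residues: list[int] | None = None,
    window: tuple[float, float, float] | None = None,
    mass_weighted: bool = True,
) -> FeatureMatrix:
    """All-pairs (i<j, lexicographic) side-chain distance matrix."""
    if residues is None:
        residues = frames.residue_ids()
    if len(residues) < 2:
        raise ValueError("need at least 2 residues")
    if window is None:
        window = (
            float(frames.times[0]),
            float(frames.times[-1]),
            float(frames.times[1] - frames.times[0]) if frames.n_frames > 1 else 1.0,
        )
    grid = time_grid(*window)
    idx = _grid_frame_indices(frames.times, grid)
    centers, residues = sidechain_centers(frames, residues, mass_weighted)
    centers = centers[idx]  # (n_steps, n_res, 3)

    mol_of = dict(
        frames.atoms.drop_duplicates("resid")[["resid", "molecule"]].itertuples(index=False)
    )
    pairs, pair_molecules, rows = [], [], []
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            pairs.append((residues[a], residues[b]))
            pair_molecules.append((mol_of[residues[a]], mol_of[residues[b]]))
            rows.append(np.linalg.norm(centers[:, a, :] - centers[:, b, :], axis=1))
    return FeatureMatrix(pairs, np.asarray(rows), window, pair_molecules)


# ---------------------------------------------------------------------------
# RMSF / RMSD


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``ref`` (both centered copies)."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    H = mc.T @ rc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return mc @ R + ref.mean(axis=0)


def _select_atom_indices(frames: TrajectoryFrames, selection: str, resid_range=None) -> np.ndarray:
    atoms = frames.atoms
    mask = atoms["name"] == selection
    if resid_range is not None:
        lo, hi = resid_range
        mask &= (atoms["resid"] >= lo) & (atoms["resid"] <= hi)
    return np.flatnonzero(mask.values)


def compute_rmsf(
    frames: TrajectoryFrames, selection: str = "CA", superpose: bool = True
) -> pd.DataFrame:
    """Per-residue RMSF of the selected atom about its time-average position.

    Each frame is least-squares superposed onto the time-average structure
    (one pass) before the fluctuations are measured.
    """
    if frames.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _select_atom_indices(frames, selection)
    missing = set(frames.residue_ids()) - set(frames.atoms["resid"].values[idx])
    if missing:
        warnings.warn(f"residues without atom {selection!r} skipped: {sorted(missing)}")
    X = frames.coords[:, idx, :]
    if superpose:
        ref = X.mean(axis=0)
        X = np.stack([_kabsch(f, ref) for f in X])
    mean = X.mean(axis=0)
    rmsf = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    return pd.DataFrame(
        {"resid": frames.atoms["resid"].values[idx], "rmsf": rmsf}
    ).reset_index(drop=True)


def compute_rmsd(
    frames: TrajectoryFrames,
    reference: int = 0,
    selection: str = "CA",
    resid_range: tuple[int, int] | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD against a reference frame over the selected atoms."""
    idx = _select_atom_indices(frames, selection, resid_range)
    if len(idx) == 0:
        raise ValueError(f"no atoms match selection {selection!r}")
    X = frames.coords[:, idx, :]
    ref = X[reference]
    out = np.empty(frames.n_frames)
    for t, f in enumerate(X):
        g = _kabsch(f, ref) if superpose else f
        out[t] = np.sqrt(((g - ref) ** 2).sum(axis=1).mean())
    return out


# ---------------------------------------------------------------------------
# contacts


def count_contacts(
    frames: TrajectoryFrames,
    cutoff: float = 4.0,
    mode: str = "pair_frames",
    scope: str = "intra_receptor",
    region_map: RegionMap | None = None,
    min_seq_sep: int = 2,
    include_hydrogens: bool = True,
    frame_stride: int = 1,
) -> ContactTable:
    """Residue-pair contacts: any-atom minimum distance strictly below cutoff.

    ``mode="unique_pairs"`` counts distinct contacting residue pairs over
    all sampled frames; ``mode="pair_frames"`` counts (pair, frame) events.
    Sequence neighbours (|i-j| < ``min_seq_sep``) are excluded.  With a
    ``region_map``, counts are aggregated by region-label pair; otherwise
    keys are residue-number pairs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if mode not in ("unique_pairs", "pair_frames"):
        raise ValueError(f"unknown mode {mode!r}")
    if scope not in ("intra_receptor", "receptor_ligand"):
        raise ValueError(f"unknown scope {scope!r}")

    atoms = frames.atoms
    keep = np.ones(len(atoms), dtype=bool)
    if not include_hydrogens:
        keep &= (atoms["element"] != "H").values
    idx = np.flatnonzero(keep)
    resid = atoms["resid"].values[idx]
    mol = atoms["molecule"].values[idx]

    seen: dict[tuple[int, int], int] = {}
    for t in range(0, frames.n_frames, frame_stride):
        pts = frames.coords[t, idx, :]
        tree = cKDTree(pts)
        cand = tree.query_pairs(r=cutoff * (1 + 1e-9), output_type="ndarray")
        if len(cand) == 0:
            continue
        d = np.linalg.norm(pts[cand[:, 0]] - pts[cand[:, 1]], axis=1)
        cand = cand[d < cutoff]
        ri, rj = resid[cand[:, 0]], resid[cand[:, 1]]
        mi, mj = mol[cand[:, 0]], mol[cand[:, 1]]
        if scope == "intra_receptor":
            ok = (mi == "receptor") & (mj == "receptor")
        else:
            ok = mi != mj
        same_chain = mi == mj
        ok &= ~(same_chain & (np.abs(ri - rj) < min_seq_sep))
        ok &= ri != rj
        lo = np.minimum(ri[ok], rj[ok])
        hi = np.maximum(ri[ok], rj[ok])
        frame_pairs = set(zip(lo.tolist(), hi.tolist()))
        for p in frame_pairs:
            seen[p] = seen.get(p, 0) + 1

    if mode == "unique_pairs":
        events = {p: 1 for p in seen}
    else:
        events = seen

    if region_map is None:
        rows = [(a, b, c) for (a, b), c in sorted(events.items())]
    else:
        agg: dict[tuple[str, str], int] = {}
        for (a, b), c in events.items():
            la, lb = region_map[a], region_map[b]
            key = tuple(sorted((la, lb)))
            agg[key] = agg.get(key, 0) + c
        rows = [(a, b, c) for (a, b), c in sorted(agg.items())]

    counts = pd.DataFrame(rows, columns=["label_a", "label_b", "count"])
    return ContactTable(counts=counts, cutoff=cutoff, mode=mode, total=int(sum(events.values())))


def select_differential_region_pairs(
    tables: dict[str, ContactTable],
    min_count: int = 100,
    max_ratio: float = 0.1,
) -> list[tuple[str, str]]:
    """Region pairs with many contacts in one form and few in the other.

    A pair qualifies when its count exceeds ``min_count`` in both apo runs
    or in both holo runs, and the min/max count ratio is below
    ``max_ratio`` for all four apo-vs-holo comparisons.
    """
    required = {"apo1", "apo2", "holo1", "holo2"}
    if set(tables) != required:
        raise ValueError(f"need tables for {sorted(required)}, got {sorted(tables)}")

    keys: set[tuple] = set()
    for t in tables.values():
        keys |= {tuple(r) for r in t.counts[["label_a", "label_b"]].itertuples(index=False)}

    selected = []
    for key in sorted(keys, key=str):
        c = {run: tables[run].lookup(*key) for run in required}
        abundant = (c["apo1"] > min_count and c["apo2"] > min_count) or (
            c["holo1"] > min_count and c["holo2"] > min_count
        )
        if not abundant:
            continue
        ok = True
        for a in ("apo1", "apo2"):
            for h in ("holo1", "holo2"):
                lo, hi = sorted((c[a], c[h]))
                ratio = lo / hi if hi > 0 else 0.0
                if ratio >= max_ratio:
                    ok = False
        if ok:
            selected.append(key)
    return selected
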