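"""Synthetic trajectory generator with planted signaling residues.

The DIO pipeline consumes only per-residue-pair distance time series, so
any stationary fluctuation model with controllable, residue-localised
perturbations exercises every stage.  Residues are placed on a reference
geometry (a ring with Cα-like 3.8 Å spacing, or an ideal helix) with a
backbone proxy atom (CA) and a short side chain (CB, CG); every atom
fluctuates around its reference position as an independent
Ornstein–Uhlenbeck (OU) process, whose closed-form stationary statistics
make oracle checks possible.  A *holo* trajectory additionally perturbs
the side-chain atoms of a designated signaling set after an onset time —
a fixed mean shift plus a slow sinusoidal mode, both along the residue's
outward side-chain direction — emulating a changed fluctuation pattern
without global unfolding.

Defaults define the desk-scale study conditions: 30 residues, 3
atoms/residue, 2000 frames at 5 ps, 0.5 Å baseline fluctuation, and a
3 Å shift + 1 Å slow mode on 3 planted residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .md_features import TrajectoryFrames

__all__ = ["Effect", "SynthConfig", "generate_apo", "generate_holo", "write_fixture"]

_CARBON = 12.011


@dataclass(frozen=True)
class Effect:
    """Holo-specific perturbation applied to signaling side chains.

    Both components act along the residue's outward side-chain direction,
    so the distance response across a residue's partners is sign-coherent
    (the side chain swings outward and oscillates radially) — the
    geometry that makes a signaling residue's pairs share one DIO shape.
    """

    mean_shift: float = 3.0  # Å, along the outward side-chain direction
    slow_mode_amplitude: float = 1.0  # Å
    slow_mode_period: float = 2.0  # ns
    onset: float = 2.0  # ns

    def __post_init__(self) -> None:
        if min(self.mean_shift, self.slow_mode_amplitude, self.slow_mode_period) < 0:
            raise ValueError("effect magnitudes must be >= 0")

    @property
    def is_null(self) -> bool:
        return self.mean_shift == 0.0 and self.slow_mode_amplitude == 0.0


@dataclass(frozen=True)
class SynthConfig:
    n_residues: int = 30
    atoms_per_residue: int = 3  # CA + side-chain atoms
    n_frames: int = 2000
    frame_interval: float = 0.005  # ns
    geometry: str = "ring"
    baseline_sd: float = 0.5  # Å, stationary OU sd per coordinate
    relaxation_time: float = 0.05  # ns, OU relaxation (<< window)
    signaling_set: tuple[int, ...] = (5, 12, 21)
    effect: Effect = field(default_factory=Effect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.atoms_per_residue < 2:
            raise ValueError("need a backbone proxy plus at least one side-chain atom")
        if self.geometry not in ("ring", "helix"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        bad = [r for r in self.signaling_set if not (1 <= r <= self.n_residues)]
        if bad:
            raise ValueError(f"signaling residues outside 1..{self.n_residues}: {bad}")


_SIDECHAIN_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH"]


def _reference_geometry(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Reference coordinates (n_atoms, 3) and per-residue outward directions."""
    n = config.n_residues
    spacing = 3.8  # Å, consecutive-residue backbone distance
    if config.geometry == "ring":
        radius = spacing / (2.0 * np.sin(np.pi / n))
        theta = 2.0 * np.pi * np.arange(n) / n
        backbone = np.stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)], axis=1
        )
        outward = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    else:  # ideal alpha-helix trace: rise 1.5 Å, 100° per residue
        turn = np.deg2rad(100.0) * np.arange(n)
        backbone = np.stack(
            [2.3 * np.cos(turn), 2.3 * np.sin(turn), 1.5 * np.arange(n)], axis=1
        )
        outward = np.stack([np.cos(turn), np.sin(turn), np.zeros(n)], axis=1)
    coords = []
    for r in range(n):
        coords.append(backbone[r])
        for a in range(1, config.atoms_per_residue):
            coords.append(backbone[r] + outward[r] * 1.5 * a)
    return np.asarray(coords), outward


def _roster(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for r in range(1, config.n_residues + 1):
        rows.append((r, "ALA", "CA", "C", _CARBON, "receptor"))
        for a in range(1, config.atoms_per_residue):
            rows.append((r, "ALA", _SIDECHAIN_NAMES[(a - 1) % 6], "C", _CARBON, "receptor"))
    return pd.DataFrame(
        rows, columns=["resid", "resname", "name", "element", "mass", "molecule"]
    )


def _ou_paths(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Stationary OU noise (n_frames, n_atoms, 3): sd baseline_sd, AR(1) in time."""
    n_atoms = config.n_residues * config.atoms_per_residue
    sd = config.baseline_sd
    shape = (config.n_frames, n_atoms, 3)
    if sd == 0.0:
        return np.zeros(shape)
    phi = np.exp(-config.frame_interval / config.relaxation_time)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    out = np.empty(shape)
    out[0] = rng.normal(0.0, sd, size=shape[1:])
    for t in range(1, config.n_frames):
        out[t] = phi * out[t - 1] + rng.normal(0.0, innov_sd, size=shape[1:])
    return out


def _frames_from_noise(config: SynthConfig, noise: np.ndarray) -> TrajectoryFrames:
    ref, _ = _reference_geometry(config)
    times = np.arange(config.n_frames) * config.frame_interval
    return TrajectoryFrames(ref[None, :, :] + noise, times, _roster(config))


def generate_apo(config: SynthConfig) -> TrajectoryFrames:
    """Unperturbed trajectory: reference geometry + stationary OU noise."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    return _frames_from_noise(config, _ou_paths(config, rng))


def generate_holo(config: SynthConfig) -> tuple[TrajectoryFrames, set[int]]:
    """Perturbed trajectory plus the ground-truth signaling residue set.

    Side-chain atoms of signaling residues acquire, after the onset time,
    a fixed mean shift plus an additive slow sinusoidal mode, both along
    the residue's outward side-chain direction.  The noise stream differs
    from the apo one, so a zero effect yields an independent draw from
    the same distribution.
    """
    streams = np.random.SeedSequence(config.seed).spawn(2)
    noise = _ou_paths(config, np.random.default_rng(streams[1]))
    eff = config.effect
    if not eff.is_null and config.signaling_set:
        _, outward = _reference_geometry(config)
        times = np.arange(config.n_frames) * config.frame_interval
        active = times >= eff.onset
        apr = config.atoms_per_residue
        for r in config.signaling_set:
            u = outward[r - 1]
            wave = np.zeros(config.n_frames)
            if eff.slow_mode_period > 0:
                wave[active] = eff.slow_mode_amplitude * np.sin(
                    2.0 * np.pi * (times[active] - eff.onset) / eff.slow_mode_period
                )
            shift = active.astype(float) * eff.mean_shift
            # side-chain atoms only: indices 1..apr-1 within the residue block
            atom_idx = [(r - 1) * apr + a for a in range(1, apr)]
            noise[:, atom_idx, :] += (shift + wave)[:, None, None] * u[None, None, :]
    return _frames_from_noise(config, noise), set(config.signaling_set)


def write_fixture(frames: TrajectoryFrames, path: str) -> None:
    """Write frames as a multi-model PDB (round-trips through load_trajectory).

    Ligand-tagged residues are written to chain L, receptor residues to
    chain A, so the molecule tags survive the round trip.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    atoms = frames.atoms
    resid_order = atoms["resid"].drop_duplicates().tolist()
    res_index = {r: i for i, r in enumerate(resid_order)}
    u = mda.Universe.empty(
        n_atoms=len(atoms),
        n_residues=len(resid_order),
        atom_resindex=[res_index[r] for r in atoms["resid"]],
        residue_segindex=[0] * len(resid_order),
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["name"].tolist())
    u.add_TopologyAttr("elements", atoms["element"].tolist())
    u.add_TopologyAttr("masses", atoms["mass"].tolist())
    u.add_TopologyAttr(
        "resnames",
        atoms.drop_duplicates("resid")["resname"].tolist(),
    )
    u.add_TopologyAttr("resids", resid_order)
    mol_of = dict(
        atoms.drop_duplicates("resid")[["resid", "molecule"]].itertuples(index=False)
    )
    u.add_TopologyAttr(
        "chainIDs",
        ["L" if mol_of[r] == "ligand" else "A" for r in atoms["resid"]],
    )
    u.load_new(frames.coords.astype(np.float32), format=MemoryReader, order="fac")
    with mda.Writer(path, multiframe=True) as writer:
        for _ in u.trajectory:
            writer.write(u.atoms)
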