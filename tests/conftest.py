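import numpy as np
import pandas as pd
import pytest

from dioscope.md_features import TrajectoryFrames


def make_frames(coords, resids=None, names=None, elements=None, masses=None, molecules=None, times=None):
    """Build a TrajectoryFrames from raw coordinate arrays for toy systems."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    resids = list(resids) if resids is not None else [i + 1 for i in range(n_atoms)]
    names = list(names) if names is not None else ["CB"] * n_atoms
    elements = list(elements) if elements is not None else ["C"] * n_atoms
    masses = list(masses) if masses is not None else [12.011] * n_atoms
    molecules = list(molecules) if molecules is not None else ["receptor"] * n_atoms
    times = np.asarray(times, dtype=float) if times is not None else np.arange(coords.shape[0], dtype=float)
    atoms = pd.DataFrame(
        {
            "resid": resids,
            "resname": ["ALA"] * n_atoms,
            "name": names,
            "element": elements,
            "mass": masses,
            "molecule": molecules,
        }
    )
    return TrajectoryFrames(coords, times, atoms)


@pytest.fixture
def two_residue_frames():
    """Two single-atom residues 5 Å apart, static over 3 frames."""
    frame = [[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]]
    return make_frames([frame] * 3, resids=[1, 2])
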