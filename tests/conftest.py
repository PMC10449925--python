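import numpy as np
import pytest

from proteinglue.trajectory import TrajectoryFrame


def make_frame(
    positions,
    groups=None,
    names=None,
    masses=None,
    residue_ids=None,
    residue_names=None,
    time=0.0,
    box=(10.0, 10.0, 10.0),
):
    """Build a TrajectoryFrame from bare coordinates with sensible defaults."""
    xyz = np.asarray(positions, dtype=float)
    n = len(xyz)
    return TrajectoryFrame(
        time=time,
        atom_ids=np.arange(1, n + 1),
        atom_names=np.asarray(names if names is not None else ["C"] * n),
        residue_ids=np.asarray(
            residue_ids if residue_ids is not None else np.arange(1, n + 1)
        ),
        residue_names=np.asarray(
            residue_names if residue_names is not None else ["ALA"] * n
        ),
        groups=np.asarray(groups if groups is not None else ["protein"] * n),
        xyz=xyz,
        masses=np.asarray(masses if masses is not None else [12.0] * n, dtype=float),
        box=np.asarray(box, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
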