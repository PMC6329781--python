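import numpy as np
import pytest

from alphastrand.synthetic_data import build_backbone, frame_from_backbone
from alphastrand.trajectory_io import Frame, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def peptide_frame(dihedrals, residue_names=None, model_index=0, first_residue_seq=1):
    """Frame with an ideal backbone built from (phi, psi) pairs."""
    coords = build_backbone(dihedrals)
    return frame_from_backbone(
        coords,
        residue_names=residue_names,
        model_index=model_index,
        first_residue_seq=first_residue_seq,
    )


@pytest.fixture
def tripeptide_frame():
    """Three residues with the middle one in the left-handed quadrant."""
    return peptide_frame([(-60.0, -45.0), (60.0, 45.0), (-60.0, -45.0)])


@pytest.fixture
def small_trajectory():
    """Five frames of a 5-residue peptide with slowly varying dihedrals."""
    frames = []
    for f in range(5):
        di = [(-60.0 - f, -45.0), (60.0, 45.0 + f), (-60.0, -45.0),
              (-120.0, 130.0), (-75.0, 150.0)]
        frames.append(peptide_frame(di, model_index=f))
    return Trajectory(frames, frame_interval_ps=10.0)
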