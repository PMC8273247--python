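import numpy as np
import pytest

from uimtools import demo_uim3_construct
from uimtools.ensemble import ConformerEnsemble
from uimtools.synthetic import HelixProfile, generate_helix_coil_ensemble


@pytest.fixture(scope="session")
def demo_seq():
    return demo_uim3_construct()


@pytest.fixture(scope="session")
def small_ensemble(demo_seq):
    """200-frame mixed helix/coil ensemble of the demo construct."""
    profile = HelixProfile.with_motif(
        len(demo_seq), 0.2,
        slice(demo_seq.index_of(336), demo_seq.index_of(350) + 1), 0.6)
    return generate_helix_coil_ensemble(demo_seq, profile, 200, seed=42)


def all_helix_ensemble(seq, n_frames=5, jitter=0.0, seed=0):
    profile = HelixProfile.flat(len(seq), 1.0, jitter_sd=jitter)
    return generate_helix_coil_ensemble(seq, profile, n_frames, seed)


def all_coil_ensemble(seq, n_frames=5, seed=0):
    profile = HelixProfile.flat(len(seq), 0.0)
    return generate_helix_coil_ensemble(seq, profile, n_frames, seed)


def ensemble_from_frames(seq, dihedral_frames):
    return ConformerEnsemble.from_dihedrals(seq, np.asarray(dihedral_frames))
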