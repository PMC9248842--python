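import numpy as np
import pytest

import registercheck as rc


@pytest.fixture(scope="session")
def helix_fixture():
    """A 40-residue helical model and its band-limited synthetic map
    (map and model share one coordinate frame)."""
    rng = np.random.default_rng(3)
    seq = rc.random_sequence(rng, 40)
    model = rc.build_helix_model(seq)
    volume = rc.synthesize_map(model, resolution=2.5, voxel=1.0)
    return seq, model, volume


@pytest.fixture()
def poly_ala_pdb(tmp_path):
    """Minimal hand-written PDB: one 12-residue poly-alanine chain."""
    lines = []
    serial = 1
    for i in range(12):
        x = 3.8 * i
        for name, dx in (("N", -0.8), ("CA", 0.0), ("C", 0.8), ("O", 1.2)):
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} ALA A{i + 1:4d}    "
                f"{x + dx:8.3f}{1.0:8.3f}{1.0:8.3f}  1.00 10.00           "
                f"{name[0]}")
            serial += 1
    lines.append("END")
    path = tmp_path / "polyala.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
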