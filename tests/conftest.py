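import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20210219)


@pytest.fixture
def larmor_bundle():
    """One-center 1s closed-shell bundle with zero magnetic response."""
    from sigmadens.models import make_min_bundle

    return make_min_bundle(
        ["He"], [[0.4, -0.2, 0.3]], [0.9], [[2.0]], np.zeros((3, 1, 1))
    )


@pytest.fixture
def two_center_bundle(rng):
    from oracles import random_two_center_bundle

    return random_two_center_bundle(rng)


@pytest.fixture
def benzene_xyz(tmp_path):
    """Idealized benzene geometry in angstrom (C-C 1.3949, C-H 1.0800)."""
    rc, rh = 1.3949, 1.3949 + 1.08
    lines = ["12", "benzene, idealized D6h (angstrom)"]
    for r, sym in ((rc, "C"), (rh, "H")):
        for k in range(6):
            a = np.pi / 3 * k
            lines.append(
                f"{sym} {r*np.cos(a):.10f} {r*np.sin(a):.10f} 0.0"
            )
    p = tmp_path / "benzene.xyz"
    p.write_text("\n".join(lines) + "\n")
    return p
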