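import warnings

import numpy as np
import pytest

from patchsol.builders import build_polymer, ideal_helix_backbone
from patchsol.pipeline import RunConfig, compute_patches
from patchsol.structure_io import assign_charges

warnings.filterwarnings("ignore", message=".*charge-center.*")


@pytest.fixture(scope="session")
def helix_KDE():
    """20-residue helix with K10, D14, E17 — small charged test protein."""
    seq = list("A" * 20)
    seq[9], seq[13], seq[16] = "K", "D", "E"
    return build_polymer(ideal_helix_backbone(20), "".join(seq))


@pytest.fixture(scope="session")
def helix_KDE_charged(helix_KDE):
    return assign_charges(helix_KDE)


@pytest.fixture(scope="session")
def epo_variant_profiles():
    """Patch results for the synthetic EPO model and its designed variants,
    with the threshold tuned once so the wild type sits at ratio 1.49."""
    from patchsol.synthetic_epo import TABLE_VARIANTS, build_synthetic_epo

    cfg = RunConfig()
    patches = {}
    for name in TABLE_VARIANTS:
        patches[name] = compute_patches(build_synthetic_epo(name), cfg).patches
    threshold = patches["WT"].posQmax / 1.49
    ratios = {name: p.posQmax / threshold for name, p in patches.items()}
    return {"patches": patches, "threshold": threshold, "ratios": ratios}
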