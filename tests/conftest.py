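import numpy as np
import pytest

from braincbir import (
    PhantomConfig,
    RunConfig,
    generate_phantoms,
    learn_dictionary,
    sample_patches_dense,
)
from braincbir.preprocess import normalize_intensity


@pytest.fixture(scope="session")
def tiny_phantoms():
    """12 phantom slices: 2 patients per class, 2 slices each."""
    return generate_phantoms(
        PhantomConfig(n_patients_per_class=2, slices_per_patient=2, seed=3)
    )


@pytest.fixture(scope="session")
def tiny_dictionary(tiny_phantoms):
    """A 20-word dictionary learned from the tiny phantom set (w=7, stride=3)."""
    descs = np.concatenate(
        [
            sample_patches_dense(normalize_intensity(r.image), r.roi, 7, 3).descriptors
            for r in tiny_phantoms
        ]
    )
    return learn_dictionary(descs, V=20, seed=0, w=7)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale pipeline configuration used by the end-to-end smoke tests."""
    return RunConfig(
        V=20,
        stride=3,
        k=1,
        partition_t_max=30,
        metric_t_max=40,
        monitor_interval=10,
        dict_patch_cap=2000,
        n_folds=2,
        prec_ns=(3,),
        seed=5,
    )
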