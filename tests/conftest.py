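import numpy as np
import pytest

from radiogen.cohort import CohortSpec, GeneSpec, simulate_cohort

TINY_SHAPE = (8, 16, 16)        # smallest shape the 3-stage generator supports


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 patients, 8x16x16 volumes, one gene and a lesion effect on the
    same latent axis; small enough for fast training smoke tests."""
    ld = 5
    effect = np.zeros(ld)
    effect[0] = 3.0
    lesion = np.zeros(ld)
    lesion[0] = 2.0
    spec = CohortSpec(n_patients=12, latent_dim=ld, volume_shape=TINY_SHAPE,
                      gene_specs=[GeneSpec("TP53", effect, 0.0)],
                      lesion_effect=lesion, noise_sd=0.05, seed=11)
    return simulate_cohort(spec)


def num_grad(f, x, eps=1e-3):
    """Central finite differences of scalar f() w.r.t. array x (mutated)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
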