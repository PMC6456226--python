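import numpy as np
import pytest

from crossconn import Area, Connectome, SyntheticSpec, generate_cortex


def make_connectome(status, cyto=None, coords=None, species="testium", **kw):
    """Build a small square connectome from a status matrix."""
    status = np.asarray(status, dtype=np.int8)
    n = status.shape[0]
    if cyto is None:
        cyto = np.arange(1, n + 1, dtype=float)
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    rc = (coords[:, 0] - coords[:, 0].min())
    rc = rc / rc.max() if rc.max() > 0 else rc
    areas = [
        Area(id=f"a{i}", cyto=float(cyto[i]), coords=coords[i], rostrocaudal=float(rc[i]))
        for i in range(n)
    ]
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    return Connectome(areas=areas, status=status, distance=dist, species=species, **kw)


@pytest.fixture
def tri_connectome():
    """3 areas, all off-diagonal statuses known and present."""
    status = np.ones((3, 3), dtype=np.int8)
    np.fill_diagonal(status, 0)
    return make_connectome(status)


@pytest.fixture(scope="session")
def std_cortex():
    """A mid-size synthetic cortex with clear wiring and laminar signal."""
    spec = SyntheticSpec(
        n_areas=60, seed=11, beta0=0.5, beta_d=-3.0, beta_c=-2.0,
        nsg_slope=30.0, nsg_noise_sd=5.0,
    )
    return generate_cortex(spec)


@pytest.fixture(scope="session")
def planted_cortex():
    """Sparse cortex with a planted reciprocal 7-clique."""
    # beta0/seed chosen so the sampled graph is strongly connected
    spec = SyntheticSpec(
        n_areas=45, seed=5, beta0=-1.2, beta_d=-2.0, beta_c=-1.0,
        planted_core_size=7,
    )
    return generate_cortex(spec)
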