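import numpy as np
import pytest

from imitatebci.effector import ChainModel, Joint


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planar_1link():
    """One revolute joint about z, unit link along x."""
    return ChainModel(
        joints=(Joint(np.array([0.0, 0.0, 1.0]), 1.0),),
        markers={"tip": (0, 1.0)},
    )


@pytest.fixture
def chain_3link():
    z, y = np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])
    return ChainModel(
        joints=(Joint(z, 1.0), Joint(y, 0.8), Joint(z, 0.5)),
        markers={"tip": (2, 0.5), "mid": (1, 0.4)},
    )


def random_dataset(rng, n_neurons=6, n_dof=3, trials=(8, 12)):
    """A synthetic aggregated dataset with i.i.d. regressors (not generated by
    any closed loop; used where only the algebra matters)."""
    from imitatebci.updates import Dataset

    ds = Dataset(n_neurons, n_dof)
    for T in trials:
        ds.append_trial(
            rng.standard_normal((T, n_dof)),
            rng.standard_normal((T, n_dof)),
            rng.standard_normal((T, n_neurons)),
            rng.standard_normal((T, n_dof)),
        )
    return ds
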