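import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sugarglass import sandbox
from sugarglass.synthetic import CompositionSpec, SyntheticSpec, toy_mixture_builder

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def umbrella_windows():
    """One umbrella ladder on the reference double well (shared, seed 11)."""
    return sandbox.run_umbrella_windows(11)


@pytest.fixture(scope="session")
def wham_profile(umbrella_windows):
    from sugarglass.free_energy import wham_pmf
    return wham_pmf(umbrella_windows)


@pytest.fixture(scope="session")
def metad_run():
    """One well-tempered metadynamics run on the reference double well."""
    return sandbox.run_metad(11)


@pytest.fixture(scope="session")
def metad_profile(metad_run):
    from sugarglass.free_energy import metad_fes_reweighted
    return metad_fes_reweighted(metad_run.hills, metad_run.z, sandbox.FES_GRID,
                                from_fraction=sandbox.METAD_TAIL_FROM,
                                reflect=sandbox.DOMAIN)


@pytest.fixture(scope="session")
def small_mixture():
    """2 model sugars + 80 waters at liquid-like toy density."""
    comp = CompositionSpec(2, 80)
    topo, frame = toy_mixture_builder(comp, SyntheticSpec(seed=7, cell=(2.3, 2.3, 2.3)))
    return topo, frame


def random_water_box(n_molecules, cell=(3.0, 3.0, 3.0), seed=0):
    """Waters at uniform random positions/orientations (no packing rules)."""
    from sugarglass.templates import merge_templates, water_template
    from sugarglass.core import Frame, UnitCell
    from sugarglass.synthetic import _random_rotation

    rng = np.random.default_rng(seed)
    wt, wpos = water_template()
    parts = []
    L = np.asarray(cell)
    for _ in range(n_molecules):
        rot = _random_rotation(rng)
        parts.append((wt, wpos @ rot.T + rng.uniform(size=3) * L))
    topo, pos = merge_templates(parts)
    return topo, Frame(time=0.0, positions=pos, cell=UnitCell(tuple(cell)))
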