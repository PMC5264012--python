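import numpy as np
import pytest

from morphosim import scenarios
from morphosim.configio import build_from_dict
from morphosim.state_core import BodyParticle, Cell, LigandField, Tissue


@pytest.fixture(scope="session")
def toggle_config_dict():
    return scenarios.scenario_config("toggle_switch_small")


@pytest.fixture(scope="session")
def toggle_parts(toggle_config_dict):
    return build_from_dict(toggle_config_dict)


@pytest.fixture
def small_tissue():
    """Ten cells with fully populated molecular state, plus two body particles."""
    rng = np.random.default_rng(42)
    cells = []
    for i in range(10):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        cells.append(Cell(
            id=i, position=rng.uniform(0, 50, 3), radii=(6.0, 6.0),
            archetype="MEI"[i % 3], polarization_axis=u,
            proteins={"A": float(rng.uniform()), "B": float(rng.uniform())},
            gene_activity={"gA": i % 2}, receptors={"R": 1.0},
            surface_ligands={"Delta": float(rng.uniform())},
            adhesion_density={"cad": 0.5}, cycle_phase=float(rng.uniform()),
            rng_stream=i))
    bodies = [
        BodyParticle(id=100, position=np.array([0.0, 0.0, -30.0]),
                     body="yolk_membrane", radius=8.0),
        BodyParticle(id=101, position=np.array([0.0, 0.0, 60.0]),
                     body="EVL", radius=7.0),
    ]
    fields = {"L": LigandField(name="L", q={i: float(i) for i in range(10)},
                               D=60.0, gamma=0.05)}
    return Tissue(cells=cells, bodies=bodies, time=12.5, ligand_fields=fields)


def random_cloud(n, seed, box=60.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, box, size=(n, 3))


def mixed_tissue(n=200, seed=0):
    """Random tissue with mesenchymal, epithelial and idle thirds."""
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n):
        cells.append(Cell(id=i, position=rng.uniform(0, 70, 3),
                          proteins={"Ubi": float(i % 3 == 0),
                                    "Epi": float(i % 3 == 1)},
                          rng_stream=i))
    return Tissue(cells=cells)


def mixed_grn():
    from morphosim.state_core import (BehaviourSpec, EpithelialPopulation,
                                      GRNSpec, OutputsSpec, SpeciesDef,
                                      parse_logic)
    return GRNSpec(
        species=[SpeciesDef("Ubi"), SpeciesDef("Epi"),
                 SpeciesDef("Lig", kind="diffusible_ligand")],
        outputs=OutputsSpec(
            archetype_M=parse_logic("Ubi>=0.5"),
            archetype_E=[EpithelialPopulation("Epi", parse_logic("Epi>=0.5"))],
            behaviour=BehaviourSpec(protrusion_polarity="bi", phi=0.5,
                                    polarization_mode="blebbing")))
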