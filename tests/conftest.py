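"""Shared fixtures: synthetic structures and (expensive) design runs are built
once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from burion import design, energy, ionpairs
from burion.fixtures import glu_lys_bundle
from burion.structure import Atom, Residue, StructureModel


def make_atom(serial, name, coords, element=None, occupancy=1.0, altloc=""):
    return Atom(serial=serial, name=name,
                element=element or name.strip()[0],
                coords=np.asarray(coords, float),
                occupancy=occupancy, altloc=altloc)


def single_residue_model(resname, atoms, chain="A", resnum=1, identifier="toy"):
    res = Residue(chain, resnum, "", resname, atoms)
    return StructureModel(identifier=identifier, chains={chain: [res]})


@pytest.fixture(scope="session")
def bundle_and_pair():
    """Default Glu/Lys four-helix bundle, side chains relaxed, pair detected."""
    model, _ = glu_lys_bundle()
    relaxed = energy.minimize(model, n_steps=500, move_backbone=False).model
    pairs = ionpairs.detect_ion_pairs(relaxed)
    assert pairs, "fixture must contain a detectable ion-pair"
    pair = sorted(pairs, key=lambda p: p.min_contact_distance)[0]
    return relaxed, pair


@pytest.fixture(scope="session")
def design_trajectories(bundle_and_pair):
    """The scaled directed-design experiment: 50 trajectories x 60 MC steps at
    310 K with weights (0.48, 0.48, 0.02), seeds 1-50."""
    model, pair = bundle_and_pair
    trajs = []
    for seed in range(1, 51):
        cfg = design.DesignConfig(n_steps=60, rng_seed=seed, minimize_steps=150)
        trajs.append(design.run_design(model, pair, cfg))
    return trajs


@pytest.fixture(scope="session")
def biased_neighbor_dataset():
    """Structure set with a 1.3x Asn excess near the implanted pair, sized to
    give >= 10,000 neighbour draws."""
    from burion.fixtures import synth_neighbor_dataset
    models, truth = synth_neighbor_dataset(
        n_structures=170, composition_bias={"ASN": 1.3}, rng_seed=7)
    return models, truth
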