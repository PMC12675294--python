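"""Shared fixtures: synthetic vessel cohorts and a small trained model.

Everything is generated programmatically and seeded; the session-scoped
trained model is shared by the tests that need a non-trivial flow
(inverse-consistency, latent inference, generative probes).
"""

from __future__ import annotations

import numpy as np
import pytest

import vesselflow as vf
from vesselflow.fixtures import default_aorta_like_spec, make_cohort, make_tube
from vesselflow.network import NetConfig
from vesselflow.trainer import TrainConfig, train


def random_cloud(rng, n, normals=False, label=""):
    pts = rng.uniform(0.0, 1.0, (n, 3))
    w = rng.uniform(0.5, 1.5, n)
    w /= w.sum()
    nr = None
    if normals:
        nr = rng.normal(size=(n, 3))
        nr /= np.linalg.norm(nr, axis=1, keepdims=True)
    return vf.WeightedPointCloud(pts, w, nr, label=label)


@pytest.fixture(scope="session")
def tube_mesh():
    return make_tube(default_aorta_like_spec(n_circ=16, n_long=24))


@pytest.fixture(scope="session")
def toy_cohort():
    """Five normalized vessel clouds + template; shapes 0-3 train, 4 is held out."""
    spec = default_aorta_like_spec(n_circ=18, n_long=36)
    meshes = make_cohort(spec, 5, variation_scale=0.1, seed=101)
    template = vf.mesh_to_weighted_cloud(make_tube(spec), label="template")
    clouds = [vf.mesh_to_weighted_cloud(m, label=f"s{i}") for i, m in enumerate(meshes)]
    cube = vf.fit_unit_cube([template] + clouds, margin=0.05)
    return {
        "template": cube.apply_cloud(template),
        "sources": [cube.apply_cloud(c) for c in clouds[:4]],
        "heldout": cube.apply_cloud(clouds[4]),
        "cube": cube,
    }


@pytest.fixture(scope="session")
def tiny_net_config():
    return NetConfig(
        fa_layers=2, fa_width=32, df_layers=3, df_width=64, n_z=32, g_z=2, n_e=3
    )


@pytest.fixture(scope="session")
def trained_toy(toy_cohort, tiny_net_config):
    """A small model trained on the 4-shape cohort (shared across tests)."""
    cfg = TrainConfig(
        epochs=100, batch_size=1, sample_points=300, lr=2e-3, K=10, seed=7
    )
    model, bank, history = train(
        toy_cohort["sources"], toy_cohort["template"], tiny_net_config, cfg
    )
    return {"model": model, "bank": bank, "history": history, "config": cfg}
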