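"""Shared fixtures.

Heavy artifacts (trained models) are session-scoped so the acceptance
tests and unit tests reuse the same runs.
"""

import numpy as np
import pandas as pd
import pytest

import neuraldfba as nd
from neuraldfba.model import LossWeights
from neuraldfba.training import TrainConfig, SplitSpec, split_forecast, train


@pytest.fixture(scope="session")
def six_panel():
    net = nd.six_substrate_panel()
    irr = nd.split_reversible(net.to_model())
    tmat = nd.build_transport(irr, net.species_order, net.species_mapping())
    return net, irr, tmat


@pytest.fixture()
def toy_table(tmp_path):
    """A 4-metabolite / 5-reaction toy model file (2 reversible)."""
    path = tmp_path / "toy.toy"
    path.write_text(
        "[metabolites]\n"
        "a_e\te\nb_e\te\nc\tc\nd\tc\n"
        "[reactions]\n"
        "upt_a\t0\t0\nupt_b\t1\t0\nconv\t1\t0\nsec\t0\t0\ngrowth\t0\t1\n"
        "[stoichiometry]\n"
        "a_e\tupt_a\t-1\nc\tupt_a\t2\n"
        "b_e\tupt_b\t-1\nc\tupt_b\t1\n"
        "c\tconv\t-1\nd\tconv\t1\n"
        "d\tsec\t-1\nb_e\tsec\t0.5\n"
        "c\tgrowth\t-3\nd\tgrowth\t-1\n"
    )
    return path


@pytest.fixture(scope="session")
def media60_experiment(six_panel):
    """The media-generalization study: 60 combinatorial media over the
    six-substrate panel, trained on 40, evaluated on the held-out 20."""
    net, irr, tmat = six_panel
    media = nd.design_media(net.substrates, "random-k", 60, seed=11)
    cfg = nd.SimConfig(seed=11)
    ds, truth = nd.generate_dataset(net, media, cfg)
    ids = ds.medium_ids
    rng = np.random.default_rng(11)
    perm = rng.permutation(len(ids))
    train_ids = [ids[i] for i in perm[:40]]
    test_ids = [ids[i] for i in perm[40:]]
    model = nd.DamnModel(tmat, irr.internal_stoichiometry(), dt=cfg.dt, seed=11)
    model, hist = train(ds.subset(train_ids), model, TrainConfig(epochs=1000, seed=11))
    return dict(ds=ds, truth=truth, model=model, hist=hist,
                train_ids=train_ids, test_ids=test_ids)


@pytest.fixture(scope="session")
def recovery_experiment(six_panel):
    """Lag-recovery study: 48 class-pure media, 32 train / 16 held out."""
    net, irr, tmat = six_panel
    media = nd.design_media(net.substrates, "random-k-pure", 48, seed=11)
    cfg = nd.SimConfig(seed=11)
    ds, truth = nd.generate_dataset(net, media, cfg)
    ids = ds.medium_ids
    rng = np.random.default_rng(11)
    perm = rng.permutation(len(ids))
    train_ids = [ids[i] for i in perm[:32]]
    test_ids = [ids[i] for i in perm[32:]]
    model = nd.DamnModel(tmat, irr.internal_stoichiometry(), dt=cfg.dt, seed=11)
    model, hist = train(ds.subset(train_ids), model, TrainConfig(epochs=1000, seed=11))
    return dict(ds=ds, truth=truth, model=model, net=net,
                train_ids=train_ids, test_ids=test_ids)


@pytest.fixture(scope="session")
def forecast_experiment():
    """Forecast study: one-substrate glucose network, 8 concentration
    levels, horizon chosen so every curve saturates within the training
    two-thirds; the model must hold the trajectory through the final
    third."""
    from neuraldfba.synthetic import Component, ToyNetwork

    net = ToyNetwork(substrates=[Component("glc", "sugar", 6, 10.0, 0.1)])
    irr = nd.split_reversible(net.to_model())
    tmat = nd.build_transport(irr, net.species_order, net.species_mapping())
    media = pd.DataFrame([
        {"medium_id": f"M{i:02d}", "species": "glc", "concentration": c}
        for i, c in enumerate([2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0])
    ])
    cfg = nd.SimConfig(seed=3, tmax=16.0)
    ds, truth = nd.generate_dataset(net, media, cfg)
    tr, te = split_forecast(ds, SplitSpec(protocol="forecast", seed=3))
    model = nd.DamnModel(tmat, irr.internal_stoichiometry(), dt=cfg.dt, seed=3)
    model, hist = train(tr, model, TrainConfig(epochs=1000, seed=3, val_mode="none"))
    return dict(ds=ds, truth=truth, model=model, train_slice=tr, test_slice=te)


@pytest.fixture(scope="session")
def diauxie_experiment():
    """Overflow study: glucose/acetate network, glucose+biomass observed."""
    net = nd.overflow_network()
    irr = nd.split_reversible(net.to_model())
    tmat = nd.build_transport(irr, net.species_order, net.species_mapping())
    media = pd.DataFrame([
        {"medium_id": f"M{i:02d}", "species": "glc", "concentration": c}
        for i, c in enumerate([8.0, 10.0, 12.0, 15.0, 18.0, 20.0])
    ])
    cfg = nd.SimConfig(seed=5, tmax=16.0)
    ds, truth = nd.generate_dataset(net, media, cfg, measured=["glc", "biomass"])
    model = nd.DamnModel(tmat, irr.internal_stoichiometry(), dt=cfg.dt, seed=5)
    model, hist = train(ds, model, TrainConfig(epochs=1000, seed=5, val_mode="none"))
    return dict(ds=ds, truth=truth, model=model, net=net, irr=irr, tmat=tmat)
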