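"""Media design, kinetic simulation, noise, and dataset round trips."""

import numpy as np
import pandas as pd
import pytest

import neuraldfba as nd
from neuraldfba.metabolic_io import load_toy_table, write_toy_table
from neuraldfba.synthetic import (
    Component,
    SimConfig,
    ToyNetwork,
    add_noise_and_replicate,
    design_media,
    primary_class,
    simulate_growth,
)


@pytest.fixture(scope="module")
def panel():
    return nd.six_substrate_panel()


class TestDesignMedia:
    def test_single_one_per_component(self, panel):
        media = design_media(panel.substrates, "single")
        assert media["medium_id"].nunique() == 6
        assert (media.groupby("medium_id").size() == 1).all()

    def test_single_three_components(self):
        comps = [Component("a", "sugar", 6, 10, 0.1),
                 Component("b", "sugar", 5, 8, 0.5),
                 Component("c", "amino_acid", 3, 6, 0.1)]
        assert design_media(comps, "single")["medium_id"].nunique() == 3

    def test_pairwise_over_three(self):
        comps = [Component(x, "sugar", 6, 10, 0.1) for x in "abc"]
        media = design_media(comps, "pairwise")
        assert media["medium_id"].nunique() == 3
        assert (media.groupby("medium_id").size() == 2).all()

    def test_random_k_distinct_and_deterministic(self, panel):
        a = design_media(panel.substrates, "random-k", 40, seed=9)
        b = design_media(panel.substrates, "random-k", 40, seed=9)
        pd.testing.assert_frame_equal(a, b)
        combos = {tuple(sorted(zip(g.species, g.concentration)))
                  for _, g in a.groupby("medium_id")}
        assert len(combos) == 40

    def test_capacity_error(self, panel):
        with pytest.raises(ValueError, match="distinct"):
            design_media(panel.substrates, "random-k", 10 ** 6)

    def test_class_pure_scheme(self, panel):
        media = design_media(panel.substrates, "random-k-pure", 20, seed=1)
        cls_of = {c.id: c.cls for c in panel.substrates}
        for _, grp in media.groupby("medium_id"):
            classes = {cls_of[s] for s in grp.species}
            assert len(classes) == 1

    def test_primary_class_carbon_weighted(self, panel):
        # 5 mM glucose (30 mM C) vs 20 mM alanine (60 mM C)
        assert primary_class({"glc": 5.0, "ala": 20.0},
                             panel.substrates) == "amino_acid"
        assert primary_class({"glc": 20.0, "ala": 5.0},
                             panel.substrates) == "sugar"


class TestSimulateGrowth:
    def test_saturated_limit_exponential_slope(self):
        """With Km ~ 0 and an open gate, ln X grows at rate Y * vmax."""
        comp = Component("s", "sugar", 6, 8.0, 1e-6)
        net = ToyNetwork(substrates=[comp])
        cfg = SimConfig(seed=0, dt=0.1, tmax=3.0, noise_sd=0.0)
        times, C, truth = simulate_growth(net, {"s": 50.0}, cfg,
                                          lag=(0.0, 1.0))
        X = C[-1]
        slope = np.polyfit(times, np.log(X), 1)[0]
        assert slope == pytest.approx(net.yield_of(comp) * comp.vmax, rel=1e-3)

    def test_zero_substrate_flat_biomass(self):
        net = nd.six_substrate_panel()
        cfg = SimConfig(seed=0, tmax=5.0)
        times, C, _ = simulate_growth(net, {"glc": 0.0}, cfg)
        assert np.allclose(C[-1], cfg.x0)

    def test_unknown_component_rejected(self):
        net = nd.six_substrate_panel()
        with pytest.raises(ValueError, match="not in network"):
            simulate_growth(net, {"mystery": 5.0}, SimConfig())

    def test_mass_balance_single_substrate(self):
        net = nd.six_substrate_panel()
        cfg = SimConfig(seed=1, tmax=24.0)
        times, C, truth = simulate_growth(net, {"glc": 10.0}, cfg)
        Y = truth["yields"]["glc"]
        dX = C[-1, -1] - C[-1, 0]
        dS = C[0, 0] - C[0, -1]
        assert dX <= Y * dS + 1e-6
        assert dX == pytest.approx(Y * dS, rel=1e-4)

    def test_substrates_never_negative(self):
        net = nd.six_substrate_panel()
        cfg = SimConfig(seed=2, tmax=24.0)
        _, C, _ = simulate_growth(net, {"glc": 5.0, "ala": 5.0}, cfg)
        assert np.all(C[:-1] >= 0.0)

    def test_lag_realism_when_gate_is_stiff(self):
        """With klag*tlag >= 5 the curve stays within 1% of total growth
        until half the lag time."""
        net = nd.six_substrate_panel()
        cfg = SimConfig(seed=3, tmax=24.0, kappa=5.0)
        tlag = 5.6
        times, C, _ = simulate_growth(net, {"glc": 15.0}, cfg,
                                      lag=(tlag, 5.0 / tlag))
        X = C[-1]
        total = X[-1] - X[0]
        i_half = int(np.argmin(np.abs(times - tlag / 2)))
        assert X[i_half] - X[0] < 0.01 * total

    def test_overflow_produces_diauxic_shape(self):
        """Byproduct rises while the source remains, falls after depletion,
        with biomass still increasing."""
        net = nd.overflow_network()
        cfg = SimConfig(seed=4, tmax=24.0)
        times, C, _ = simulate_growth(net, {"glc": 15.0}, cfg, lag=(1.0, 3.0))
        G, A, X = C[0], C[1], C[2]
        i_dep = int(np.argmax(G < 1e-3))
        assert i_dep > 0
        # rising while glucose present
        assert A[i_dep] > A[i_dep // 2] > 0
        # falling afterwards, consumed to near zero
        assert A[-1] < 0.05 * A.max()
        # biomass keeps growing through the shift
        assert X[-1] > X[i_dep] * 1.05


class TestNoise:
    def test_zero_noise_replicates_identical(self):
        net = nd.six_substrate_panel()
        cfg = SimConfig(seed=0, noise_sd=0.0, replicates=3, tmax=2.0)
        times, C, _ = simulate_growth(net, {"glc": 5.0}, cfg)
        tab = add_noise_and_replicate(times, C, net.species_order, "M0", cfg,
                                      np.random.default_rng(0), ["biomass"])
        wide = tab.pivot_table(index="time", columns="replicate",
                               values="value")
        assert np.allclose(wide[0], wide[1]) and np.allclose(wide[1], wide[2])

    def test_seeded_reproducibility(self):
        net = nd.six_substrate_panel()
        cfg = SimConfig(seed=0, noise_sd=0.05, replicates=2, tmax=2.0)
        times, C, _ = simulate_growth(net, {"glc": 5.0}, cfg)
        t1 = add_noise_and_replicate(times, C, net.species_order, "M0", cfg,
                                     np.random.default_rng(7))
        t2 = add_noise_and_replicate(times, C, net.species_order, "M0", cfg,
                                     np.random.default_rng(7))
        pd.testing.assert_frame_equal(t1, t2)

    def test_replicate_mean_converges(self):
        """Law of large numbers: the 1000-replicate mean lands within three
        standard errors of the noiseless value."""
        net = nd.six_substrate_panel()
        cfg = SimConfig(seed=0, noise_sd=0.05, replicates=1000, tmax=1.0)
        times, C, _ = simulate_growth(net, {"glc": 5.0}, cfg)
        tab = add_noise_and_replicate(times, C, net.species_order, "M0", cfg,
                                      np.random.default_rng(11), ["biomass"])
        last = tab[tab.time == times[-1]]["value"]
        target = C[-1, -1]
        se = target * cfg.noise_sd / np.sqrt(1000)
        assert abs(last.mean() - target) < 3 * se + target * cfg.noise_sd ** 2


class TestDatasetIO:
    def test_round_trip(self, tmp_path):
        net = nd.six_substrate_panel()
        media = design_media(net.substrates, "random-k", 4, seed=0)
        ds, truth = nd.generate_dataset(net, media,
                                        SimConfig(seed=0, tmax=4.0))
        ds.to_dir(str(tmp_path / "d"))
        nd.write_dataset(ds.media, ds.series, ds.mask, str(tmp_path / "d"),
                         truth=truth, network=net)
        back = nd.GrowthDataset.from_dir(str(tmp_path / "d"))
        pd.testing.assert_frame_equal(back.media, ds.media)
        pd.testing.assert_frame_equal(back.series, ds.series)
        assert back.species == ds.species and back.dt == ds.dt
        assert (tmp_path / "d" / "truth.json").exists()
        assert (tmp_path / "d" / "network.toy").exists()

    def test_masks_honored(self, tmp_path):
        net = nd.overflow_network()
        media = pd.DataFrame([{"medium_id": "M0", "species": "glc",
                               "concentration": 10.0}])
        ds, _ = nd.generate_dataset(net, media, SimConfig(seed=0, tmax=4.0),
                                    measured=["glc", "biomass"])
        assert set(ds.series.species) == {"glc", "biomass"}
        assert ds.measured_species == ["glc", "biomass"]
        target, _ = ds.target_tensor()
        assert np.all(np.isnan(target[0, 1, :]))      # acetate unmeasured
        assert np.isfinite(target[0, 0, 1:]).all()    # glucose measured

    def test_byte_determinism(self, tmp_path):
        net = nd.six_substrate_panel()
        media = design_media(net.substrates, "random-k", 3, seed=5)
        outs = []
        for sub in ("a", "b"):
            ds, _ = nd.generate_dataset(net, media, SimConfig(seed=5, tmax=3.0))
            d = tmp_path / sub
            ds.to_dir(str(d))
            outs.append((d / "series.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_network_expressible_as_toy_table(self, tmp_path):
        net = nd.overflow_network()
        model = net.to_model()
        p = tmp_path / "net.toy"
        write_toy_table(model, str(p))
        again = load_toy_table(str(p))
        assert (again.S != model.S).nnz == 0
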