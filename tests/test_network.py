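"""Network construction: scopes, probabilities, variants, delays."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from columnet.network import (BuildError, NetworkSpec, Variant,
                              VARIANT_PRESETS, build_network, reduced_spec)
from columnet.neurons import CellType
from columnet.network import TYPE_CODES

PC, BC, MC, VIP = (TYPE_CODES[t] for t in
                   (CellType.PC, CellType.BC, CellType.MC, CellType.VIP))


def _cells_of(net, code):
    return set(net.cells.index[net.cells["type"] == code])


class TestStructure:
    def test_cell_counts(self, net22):
        spec = net22.spec
        assert net22.n_cells == spec.n_cells == 4 * (6 * 36 + 8)
        counts = net22.cells["type"].value_counts()
        assert counts[PC] == 4 * 6 * 30
        assert counts[BC] == 4 * 8
        assert counts[MC] == counts[VIP] == 4 * 6 * 3

    def test_no_self_or_duplicate_edges(self, net22):
        conn = net22.connections
        assert (conn["pre"] != conn["post"]).all()
        assert not conn.duplicated(["pre", "post", "cls"]).any()

    def test_local_scopes_respected(self, net22):
        cells = net22.cells
        conn = net22.connections
        hc = cells["hc"].values
        mc = cells["mc"].values
        for cls, scope in [("PC-PC_LO", "mc"), ("PC-MC_LO", "mc"),
                           ("MC-PC", "mc"), ("VIP-MC", "mc"),
                           ("PC-BC", "hc"), ("BC-PC", "hc")]:
            e = conn[conn["cls"] == cls]
            assert (hc[e["pre"]] == hc[e["post"]]).all(), cls
            if scope == "mc":
                assert (mc[e["pre"]] == mc[e["post"]]).all(), cls

    def test_long_range_stays_on_pattern_and_leaves_hypercolumn(self, net22):
        cells = net22.cells
        for cls in ("PC-PC_LR", "PC-MC_LR"):
            e = net22.connections[net22.connections["cls"] == cls]
            assert len(e) > 0
            assert (cells["hc"].values[e["pre"]]
                    != cells["hc"].values[e["post"]]).all()
            assert (cells["mc"].values[e["pre"]]
                    == cells["mc"].values[e["post"]]).all()

    def test_long_range_out_degrees(self, net22):
        e = net22.connections
        lr_pc = e[e["cls"] == "PC-PC_LR"].groupby("pre").size()
        assert (lr_pc == 4).all()
        lr_mc = e[e["cls"] == "PC-MC_LR"].groupby("pre").size()
        assert (lr_mc == 1).all()
        n_pc = (net22.cells["type"] == PC).sum()
        assert len(lr_pc) == len(lr_mc) == n_pc

    def test_single_hypercolumn_has_no_long_range(self):
        net = build_network(NetworkSpec(grid=(1, 1), seed=0))
        cls = net.connections["cls"].astype(str)
        assert not cls.str.endswith("_LR").any()

    def test_pattern_of_is_minicolumn_index(self, net22):
        assert net22.pattern_of(3) == 3


class TestProbabilities:
    @pytest.mark.parametrize("cls, p, n_per_post", [
        ("PC-PC_LO", 0.25, 29),
        ("PC-MC_LO", 0.30, 30),
        ("MC-PC", 0.80, 3),
        ("BC-PC", 0.70, 8),
        ("PC-BC", 0.70, 180),
        ("VIP-MC", 0.60, 3),
    ])
    def test_realized_fractions_within_three_se(self, net66, cls, p,
                                                n_per_post):
        e = net66.class_edges(cls)
        post_code = TYPE_CODES[CellType(cls.split("-")[1].split("_")[0])]
        n_post = (net66.cells["type"] == post_code).sum()
        n_trials = n_post * n_per_post
        phat = len(e) / n_trials
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(phat - p) < 3 * se, (cls, phat, p)

    def test_pairwise_long_range_connectivity(self, net66):
        """P(ordered same-pattern pair carries >= 1 projection) =
        1 - (34/35)^30 ~ 0.581 on the 6x6 grid."""
        cells = net66.cells
        e = net66.connections
        lr = e[e["cls"].astype(str).str.endswith("_LR")]
        src = list(zip(cells["hc"].values[lr["pre"]],
                       cells["mc"].values[lr["pre"]],
                       cells["hc"].values[lr["post"]],
                       cells["mc"].values[lr["post"]]))
        pairs = {(a, b, c, d) for a, b, c, d in src}
        n_hc, n_mc = 36, 6
        n_ordered = n_mc * n_hc * (n_hc - 1)
        phat = len(pairs) / n_ordered
        p = 1 - (34 / 35) ** 30
        se = np.sqrt(p * (1 - p) / n_ordered)
        assert abs(phat - p) < 4 * se


class TestDeterminism:
    def test_identical_spec_identical_network(self):
        a = build_network(NetworkSpec(grid=(2, 2), seed=5))
        b = build_network(NetworkSpec(grid=(2, 2), seed=5))
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.connections, b.connections)

    def test_variants_share_pc_pc_lr_edges(self):
        """Routing variants differ only in the interneuron terminal."""
        t1 = build_network(NetworkSpec(grid=(2, 2), seed=5,
                                       variant=Variant.TYPE1))
        t5 = build_network(NetworkSpec(grid=(2, 2), seed=5,
                                       variant=Variant.TYPE5))
        a = t1.connections.query("cls == 'PC-PC_LR'")[["pre", "post"]]
        b = t5.connections.query("cls == 'PC-PC_LR'")[["pre", "post"]]
        assert a.reset_index(drop=True).equals(b.reset_index(drop=True))


class TestVariants:
    def test_preset_table(self):
        assert VARIANT_PRESETS[Variant.TYPE1] == ("MC", "facilitating",
                                                  "specific")
        assert VARIANT_PRESETS[Variant.TYPE4] == ("MC", "facilitating",
                                                  "unspecific")
        assert VARIANT_PRESETS[Variant.TYPE5] == ("none", None, "specific")
        assert VARIANT_PRESETS[Variant.TYPE6] == ("BC", "depressing",
                                                  "specific")

    def test_type5_omits_interneuron_terminals(self):
        net = build_network(NetworkSpec(grid=(2, 2), seed=3,
                                        variant=Variant.TYPE5))
        cls = net.connections["cls"].astype(str)
        assert (cls == "PC-MC_LR").sum() == 0
        assert (cls == "PC-BC_LR").sum() == 0
        assert (cls == "PC-PC_LR").sum() > 0

    def test_type2_routes_terminals_to_bc(self):
        net = build_network(NetworkSpec(grid=(2, 2), seed=3,
                                        variant=Variant.TYPE2))
        cls = net.connections["cls"].astype(str)
        assert (cls == "PC-BC_LR").sum() > 0
        assert (cls == "PC-MC_LR").sum() == 0

    def test_type4_pools_mc_across_minicolumns(self):
        net = build_network(NetworkSpec(grid=(2, 2), seed=3,
                                        variant=Variant.TYPE4))
        cells = net.cells
        e = net.connections.query("cls == 'MC-PC'")
        crossing = (cells["mc"].values[e["pre"]]
                    != cells["mc"].values[e["post"]])
        assert crossing.any()

    def test_type6_overrides_relay_dynamics(self):
        net = build_network(NetworkSpec(grid=(2, 2), seed=3,
                                        variant=Variant.TYPE6))
        assert net.stp_overrides == {"PC-MC_LO": "PC-BC",
                                     "PC-MC_LR": "PC-BC"}
        cls = net.connections["cls"].astype(str)
        assert (cls == "PC-MC_LR").sum() > 0  # minicolumn-specific relays


class TestCompensation:
    def test_type1_is_identity(self):
        net = build_network(NetworkSpec(grid=(2, 2), seed=3))
        assert np.allclose(net.connections["weight_scale"], 1.0)

    def test_type4_conserves_inhibition_product(self):
        spec = NetworkSpec(grid=(2, 2), seed=3, variant=Variant.TYPE4)
        net = build_network(spec)
        ws = net.connections.query("cls == 'MC-PC'")["weight_scale"]
        assert np.allclose(ws, 1.0 / spec.minicolumns_per_hc)

    def test_type5_rescales_local_mc_excitation(self):
        net = build_network(NetworkSpec(grid=(2, 2), seed=3,
                                        variant=Variant.TYPE5))
        ws = net.connections.query("cls == 'PC-MC_LO'")["weight_scale"]
        # reference 9 local + 10 long-range inputs -> local carries 19/9
        assert np.allclose(ws, 19.0 / 9.0)

    def test_type2_rescales_bc_excitation(self):
        net = build_network(NetworkSpec(grid=(2, 2), seed=3,
                                        variant=Variant.TYPE2))
        ws = net.connections.query("cls == 'PC-BC'")["weight_scale"]
        assert np.allclose(ws, 126.0 / (126.0 + 180.0 / 8.0))


class TestDelays:
    def test_delays_positive_and_right_skewed(self, net22):
        d = net22.connections["delay_ms"].values
        assert (d > 0).all()
        assert skew(d) > 0

    def test_zero_speed_spread_gives_distance_over_speed(self):
        spec = NetworkSpec(grid=(2, 2), seed=9, conduction_speed_sd=0.0)
        net = build_network(spec)
        xyz = net.cells[["x", "y", "z"]].values
        e = net.connections
        dist = np.linalg.norm(xyz[e["pre"].values] - xyz[e["post"].values],
                              axis=1)
        assert np.allclose(e["delay_ms"], np.maximum(dist / 300.0, 1e-3))

    def test_one_millimeter_at_reference_speed(self):
        # 1 mm at 0.3 m/s is 3.33 ms
        assert 1000.0 / 300.0 == pytest.approx(3.333, abs=1e-3)


class TestErrors:
    def test_infeasible_counts_rejected(self):
        with pytest.raises(BuildError):
            NetworkSpec(pc_per_mc=3)

    def test_reduced_preset(self):
        spec = reduced_spec(grid=(3, 3), variant=Variant.TYPE5, seed=2)
        assert spec.grid == (3, 3) and spec.variant == Variant.TYPE5


class TestSpecIO:
    def test_yaml_round_trip(self, tmp_path):
        from columnet.network import spec_from_file, spec_to_file
        spec = NetworkSpec(grid=(3, 4), seed=11, variant=Variant.TYPE4,
                           tau_facil_override=500.0)
        f = tmp_path / "spec.yaml"
        spec_to_file(spec, f)
        assert spec_from_file(f) == spec
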