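import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from reverie import (
    collapse_network,
    condition_zmap,
    make_parcel_meta,
    network_contrast,
    parcelwise_condition_contrast,
    participant_reliability_contrast,
    t_to_z,
)
from reverie.parcels import NINE_NETWORKS, SEVENTEEN_NETWORKS


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        assert t_to_z(0.0, 5) == pytest.approx(0.0, abs=1e-12)

    def test_large_df_approaches_identity(self):
        assert t_to_z(1.96, 100000) == pytest.approx(1.96, abs=1e-3)

    def test_matches_quadrature_oracle(self):
        # tail probability of t(10) beyond 2.0 by numerical integration,
        # then invert the standard-normal tail by root finding
        df = 10

        def t_pdf(x):
            c = stats.gamma.pdf  # noqa: F841 - use explicit formula below
            from math import gamma, pi, sqrt

            return (
                gamma((df + 1) / 2)
                / (sqrt(df * pi) * gamma(df / 2))
                * (1 + x**2 / df) ** (-(df + 1) / 2)
            )

        tail, _ = integrate.quad(t_pdf, 2.0, np.inf)
        z = optimize.brentq(lambda v: stats.norm.sf(v) - tail, -10, 10)
        assert t_to_z(2.0, df) == pytest.approx(z, abs=1e-8)

    def test_monotone_and_antisymmetric(self):
        ts = np.linspace(-4, 4, 21)
        zs = [t_to_z(t, 7) for t in ts]
        assert (np.diff(zs) > 0).all()
        for t in ts:
            assert t_to_z(-t, 7) == pytest.approx(-t_to_z(t, 7), abs=1e-10)

    def test_invalid_df_is_an_error(self):
        with pytest.raises(ValueError):
            t_to_z(1.0, 0)


def make_zmap(n_parcels, rng=None, delta=0.0):
    rng = rng or np.random.default_rng(0)
    z_n = rng.normal(size=n_parcels)
    z_m = z_n + delta + 0.1 * rng.normal(size=n_parcels)
    return pd.DataFrame(
        {
            "parcel_id": np.arange(n_parcels),
            "z_music": z_m,
            "z_nomusic": z_n,
            "z_diff": z_m - z_n,
        }
    )


class TestParcelwiseContrast:
    def test_identical_conditions_give_t_zero(self):
        zmap = make_zmap(10)
        zmap["z_music"] = zmap["z_nomusic"]
        zmap["z_diff"] = 0.0
        res = parcelwise_condition_contrast(zmap)
        assert res["t"] == 0.0

    def test_79_parcels_report_df_78(self):
        res = parcelwise_condition_contrast(make_zmap(79, delta=0.5))
        assert res["df"] == 78
        assert "fixed effect" in res["caveat"]

    def test_matches_closed_form_paired_t(self):
        diffs = np.array([0.3, -0.1, 0.4, 0.2, 0.0])
        zmap = pd.DataFrame(
            {
                "parcel_id": range(5),
                "z_music": diffs,
                "z_nomusic": np.zeros(5),
                "z_diff": diffs,
            }
        )
        res = parcelwise_condition_contrast(zmap)
        expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        assert res["t"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_parcels_is_an_error(self):
        with pytest.raises(ValueError, match=">= 3 parcels"):
            parcelwise_condition_contrast(make_zmap(2))


def reliability_inputs(n_per_group=24, n_parcels=6, n_scenes=10, seed=0, delta=0.0):
    rng = np.random.default_rng(seed)
    frames, recalls = [], []
    for group, shift in (("music", delta), ("nomusic", 0.0)):
        rows, rec = [], []
        for i in range(n_per_group):
            pid = f"{group}-{i:02d}"
            remembered = rng.random(n_scenes) < 0.5
            if not remembered.any() or remembered.all():
                remembered[0], remembered[-1] = True, False
            for sid in range(1, n_scenes + 1):
                rec.append(
                    {"participant_id": pid, "scene_id": sid,
                     "remembered": bool(remembered[sid - 1])}
                )
            for k in range(n_parcels):
                for sid in range(1, n_scenes + 1):
                    z = rng.normal() + (shift if remembered[sid - 1] else 0.0)
                    rows.append(
                        {"participant_id": pid, "parcel_id": k,
                         "scene_id": sid, "z": z}
                    )
        frames.append(pd.DataFrame(rows))
        recalls.append(pd.DataFrame(rec))
    return frames[0], frames[1], recalls[0], recalls[1]


class TestParticipantReliabilityContrast:
    def test_24_plus_24_participants_report_df_46(self):
        sm, sn, rm, rn = reliability_inputs()
        res = participant_reliability_contrast(sm, sn, rm, rn)
        assert res["df"] == 46

    def test_identical_groups_give_t_near_zero(self):
        sm, sn, rm, rn = reliability_inputs(seed=1)
        # use the music frame for both conditions (relabelled participants)
        sn2 = sm.copy()
        res = participant_reliability_contrast(sm, sn2, rm, rm)
        assert res["t"] == pytest.approx(0.0, abs=1e-10)

    def test_planted_music_only_coupling_gives_positive_t(self):
        sm, sn, rm, rn = reliability_inputs(seed=2, delta=0.8)
        res = participant_reliability_contrast(sm, sn, rm, rn)
        assert res["t"] > 2.0


class TestNetworkContrast:
    def test_single_network_reduces_to_parcelwise(self):
        zmap = make_zmap(12, delta=0.4)
        meta = make_parcel_meta(range(12), subnetworks=["DefaultA"] * 12)
        out = network_contrast(zmap, meta)
        assert len(out) == 1
        res = parcelwise_condition_contrast(zmap)
        assert out.iloc[0]["t"] == pytest.approx(res["t"])
        assert out.iloc[0]["q"] == pytest.approx(out.iloc[0]["p"])

    def test_small_networks_are_skipped(self, caplog):
        import logging

        zmap = make_zmap(5)
        meta = make_parcel_meta(
            range(5), subnetworks=["DefaultA"] * 3 + ["VisPeri"] * 2
        )
        with caplog.at_level(logging.WARNING):
            out = network_contrast(zmap, meta)
        assert list(out["network"]) == ["Default"]
        assert "skipped" in caplog.text

    def test_effect_planted_in_one_network_ranks_top_and_survives_fdr(self):
        rng = np.random.default_rng(4)
        subnets = [SEVENTEEN_NETWORKS[i % 17] for i in range(85)]
        meta = make_parcel_meta(range(85), subnetworks=subnets)
        zmap = make_zmap(85, rng=rng)
        default = meta.loc[meta["network"] == "Default", "parcel_id"]
        zmap.loc[zmap["parcel_id"].isin(default), "z_diff"] += 1.5
        out = network_contrast(zmap, meta)
        best = out.sort_values("t", ascending=False).iloc[0]
        assert best["network"] == "Default"
        assert best["q"] < 0.05

    def test_unmapped_parcel_is_an_error(self):
        zmap = make_zmap(4)
        meta = make_parcel_meta(range(3))
        with pytest.raises(ValueError, match="without a network"):
            network_contrast(zmap, meta)


class TestNetworkCollapse:
    def test_seventeen_labels_collapse_to_nine_networks(self):
        collapsed = {collapse_network(s) for s in SEVENTEEN_NETWORKS}
        assert collapsed == set(NINE_NETWORKS)
        assert len(collapsed) == 9

    def test_visual_networks_stay_distinct(self):
        assert collapse_network("VisCent") == "VisCent"
        assert collapse_network("VisPeri") == "VisPeri"
        assert collapse_network("DefaultC") == "Default"


class TestConditionZmap:
    def test_zmap_converts_each_condition_with_its_own_df(self):
        em = pd.DataFrame({"parcel_id": [0], "t": [2.0], "n": [24]})
        en = pd.DataFrame({"parcel_id": [0], "t": [-1.0], "n": [20]})
        out = condition_zmap(em, en)
        assert out.iloc[0]["z_music"] == pytest.approx(t_to_z(2.0, 23))
        assert out.iloc[0]["z_nomusic"] == pytest.approx(t_to_z(-1.0, 19))
        assert out.iloc[0]["z_diff"] == pytest.approx(
            t_to_z(2.0, 23) - t_to_z(-1.0, 19)
        )
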