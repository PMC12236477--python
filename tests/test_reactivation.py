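import numpy as np
import pandas as pd
import pytest

from reverie import (
    CuePair,
    aggregate_pair_scores,
    build_megascenes,
    enumerate_pairs,
    pearson,
    scene_table_from_songs,
    score_parcel,
)
from reverie.patterns import scene_patterns_tensor
from reverie.reactivation import (
    _baseline_matrix,
    baseline_pair_correlations,
    permutation_rng,
)


class TestEnumeratePairs:
    def test_single_occurrence_song_has_no_pairs(self):
        table = scene_table_from_songs(["A", None, "A", "B", None, "B"])
        megas = build_megascenes(table)
        pairs = enumerate_pairs(table, megas)
        # A: scenes 1 and 3 -> pair (3, 1); B: scenes 4 and 6 -> pair (6, 4)
        assert {(p.mega_id, p.earlier_scene_id) for p in pairs} == {(2, 1), (4, 4)}

    def test_mega_compared_only_to_strictly_earlier_scenes(self):
        # 'Phone Call' pattern: earlier singles at 1 and 3, later run 5-9
        labels = ["P", None, "P", None] + ["P"] * 5
        table = scene_table_from_songs(labels)
        megas = build_megascenes(table)
        run = [m for m in megas if len(m.member_scene_ids) == 5][0]
        earlier = [
            p.earlier_scene_id for p in enumerate_pairs(table, megas)
            if p.mega_id == run.mega_id
        ]
        assert earlier == [1, 3]

    def test_no_pair_violates_the_strictly_earlier_predicate(self):
        table = scene_table_from_songs(
            ["A", "B", None, "A", "A", None, "B", "A"]
        )
        megas = build_megascenes(table)
        start = {m.mega_id: min(m.member_scene_ids) for m in megas}
        for p in enumerate_pairs(table, megas):
            assert p.earlier_scene_id < start[p.mega_id]


class TestPearson:
    def test_identical_vectors(self):
        v = np.array([0.3, -1.0, 2.0, 0.7])
        assert pearson(v, v) == pytest.approx(1.0)

    def test_negated_vector(self):
        v = np.array([0.3, -1.0, 2.0, 0.7])
        assert pearson(v, -v) == pytest.approx(-1.0)

    def test_four_voxel_toy_matches_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        # hand computation: sum of centered products = 6.5,
        # sum of squares 5.0 and 8.75
        expected = 6.5 / np.sqrt(5.0 * 8.75)
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson(np.ones(4), np.arange(4.0), context="p1/parcel 0/scene 2")


class TestBaseline:
    def test_three_participant_brute_force(self):
        # 3 no-music participants, 4-voxel patterns, 2 pool scenes, 1 mega
        rng = np.random.default_rng(5)
        pats = rng.normal(size=(3, 2, 4))
        table = scene_table_from_songs(["A", None, "A"])
        megas = build_megascenes(table)
        pool = [1, 3]
        pool_index = {1: 0, 3: 1}
        mega_later = megas[1]  # scene 3
        expected = 0.0
        for q in range(3):
            loo = (pats.sum(axis=0) - pats[q]) / 2
            mega_pat = pats[q, 1]  # single-member mega = scene pattern
            expected += pearson(mega_pat, loo[0])
        expected /= 3
        got = baseline_pair_correlations(
            pats, megas, pool_index,
            pair_mega_idx=np.array([1]), pair_scene_idx=np.array([0]),
        )
        assert got[0] == pytest.approx(expected, abs=1e-12)

    def test_two_participants_is_an_error(self):
        pats = np.random.default_rng(0).normal(size=(2, 2, 4))
        table = scene_table_from_songs(["A", None, "A"])
        megas = build_megascenes(table)
        with pytest.raises(ValueError, match=">= 3 comparison participants"):
            _baseline_matrix(pats, megas, {1: 0, 3: 1})

    def test_identical_participants_make_baseline_equal_raw(self, tiny_scenes):
        # noise-free, equal encoding: every participant's pattern identical
        from reverie import SimConfig, generate

        ds = generate(
            SimConfig(
                n_participants=3, n_parcels=1, voxels_per_parcel=12,
                scene_table=tiny_scenes, noise_sd=0.0, encoding_sd=0.0,
                react_gain=0.0, seed=1,
            )
        )
        pool = ds.scenes.repeated_music_scene_ids()
        pats = scene_patterns_tensor(ds.data["nomusic"], ds.scenes, pool, ds.tr_s)
        megas = build_megascenes(ds.scenes)
        pairs = enumerate_pairs(ds.scenes, megas)
        pool_index = {s: i for i, s in enumerate(pool)}
        mega_idx = np.array(
            [[m.mega_id for m in megas].index(p.mega_id) for p in pairs]
        )
        scene_idx = np.array([pool_index[p.earlier_scene_id] for p in pairs])
        base = baseline_pair_correlations(
            pats[:, 0], megas, pool_index, mega_idx, scene_idx
        )
        from reverie.reactivation import raw_pair_correlations

        raw = raw_pair_correlations(
            _mega(pats[0, 0], megas, pool_index),
            pats[:, 0].mean(axis=0),
            mega_idx,
            scene_idx,
        )
        np.testing.assert_allclose(base, raw, atol=1e-12)


def _mega(scene_pats, megas, pool_index):
    return np.stack(
        [
            scene_pats[[pool_index[s] for s in m.member_scene_ids], :].mean(axis=0)
            for m in megas
        ]
    )


class TestPermutationZ:
    def test_matches_naive_reimplementation(self, tiny_dataset):
        """Pipeline z-scores equal a straight-line brute-force oracle that
        materializes every shuffled contrast explicitly (shared shuffles)."""
        ds = tiny_dataset
        scenes = ds.scenes
        pool = scenes.repeated_music_scene_ids()
        megas = build_megascenes(scenes)
        pairs = enumerate_pairs(scenes, megas)
        pats_m = scene_patterns_tensor(ds.data["music"], scenes, pool, ds.tr_s)
        pats_n = scene_patterns_tensor(ds.data["nomusic"], scenes, pool, ds.tr_s)
        n_perm = 150
        k = 1
        got = score_parcel(
            pats_m[:, k], pats_n[:, k], pool, megas, pairs,
            n_perm=n_perm, seed=13, parcel_index=k, parcel_id=k,
            subject_ids=ds.participant_ids["music"],
        )
        pool_index = {s: i for i, s in enumerate(pool)}

        def contrast(p, mega, scene_idx):
            g = pats_n[:, k].mean(axis=0)
            mega_pat = np.mean(
                [pats_m[p, k, pool_index[s]] for s in mega.member_scene_ids], axis=0
            )
            raw = pearson(mega_pat, g[scene_idx])
            base = 0.0
            for q in range(3):
                loo = (pats_n[:, k].sum(axis=0) - pats_n[q, k]) / 2
                mq = np.mean(
                    [pats_n[q, k, pool_index[s]] for s in mega.member_scene_ids],
                    axis=0,
                )
                base += pearson(mq, loo[scene_idx])
            return raw - base / 3

        for p, pid in enumerate(ds.participant_ids["music"]):
            rng = permutation_rng(13, k, p)
            perms = rng.permuted(
                np.broadcast_to(np.arange(len(pool)), (n_perm, len(pool))), axis=1
            )
            for j, pair in enumerate(pairs):
                mega = [m for m in megas if m.mega_id == pair.mega_id][0]
                si = pool_index[pair.earlier_scene_id]
                true = contrast(p, mega, si)
                null = np.array([contrast(p, mega, perm[si]) for perm in perms])
                z = (true - null.mean()) / null.std(ddof=1)
                row = got[
                    (got["participant_id"] == pid)
                    & (got["mega_id"] == pair.mega_id)
                    & (got["scene_id"] == pair.earlier_scene_id)
                ].iloc[0]
                assert row["z"] == pytest.approx(z, abs=1e-10)
                assert row["contrast"] == pytest.approx(true, abs=1e-10)

    def test_too_few_permutations_is_an_error(self, tiny_dataset):
        ds = tiny_dataset
        pool = ds.scenes.repeated_music_scene_ids()
        megas = build_megascenes(ds.scenes)
        pairs = enumerate_pairs(ds.scenes, megas)
        pats = scene_patterns_tensor(ds.data["music"], ds.scenes, pool, ds.tr_s)
        patsn = scene_patterns_tensor(ds.data["nomusic"], ds.scenes, pool, ds.tr_s)
        with pytest.raises(ValueError, match="n_perm"):
            score_parcel(
                pats[:, 0], patsn[:, 0], pool, megas, pairs, n_perm=50, seed=0
            )

    def test_degenerate_null_is_an_error(self, tiny_scenes):
        # comparison patterns identical across pool scenes: the contrast is
        # the same under every shuffle, so the null has zero spread
        rng = np.random.default_rng(2)
        pool = tiny_scenes.repeated_music_scene_ids()
        megas = build_megascenes(tiny_scenes)
        pairs = enumerate_pairs(tiny_scenes, megas)
        pn = np.repeat(rng.normal(size=(3, 1, 12)), len(pool), axis=1)
        pm = rng.normal(size=(3, len(pool), 12))
        with pytest.raises(ValueError, match="degenerate"):
            score_parcel(pm, pn, pool, megas, pairs, n_perm=100, seed=0)


class TestAggregation:
    def test_pair_z_values_average_per_earlier_scene(self):
        pair_scores = pd.DataFrame(
            {
                "participant_id": ["p1"] * 3,
                "parcel_id": [0] * 3,
                "mega_id": [2, 3, 3],
                "scene_id": [1, 1, 4],
                "raw": [0.1, 0.3, 0.5],
                "baseline": [0.0, 0.0, 0.0],
                "contrast": [0.1, 0.3, 0.5],
                "z": [1.0, 3.0, 5.0],
            }
        )
        out = aggregate_pair_scores(pair_scores)
        scene1 = out[out["scene_id"] == 1].iloc[0]
        assert scene1["z"] == pytest.approx(2.0)
        assert scene1["n_pairs"] == 2
        assert out[out["scene_id"] == 4].iloc[0]["n_pairs"] == 1
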