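"""Bridge classification, frequency aggregation and group comparison tests."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mubridge.bridge import (
    CLASSES,
    bridge_frequencies,
    classify_frame,
    compare_frequencies,
    hbond_frequency,
    stacking_frequency,
)
from mubridge.frames import RoleMap
from mubridge.geometry import DEFAULT_HBOND_WINDOW

from conftest import asp_carboxylate, lig_hydroxyl, make_frame, ring_frame, water


def bridge_frame(lig_xyz, waters_xyz=()):
    records = asp_carboxylate() + [lig_hydroxyl(lig_xyz)]
    records += [water(i + 1, xyz) for i, xyz in enumerate(waters_xyz)]
    return make_frame(records)


def oracle_label(frame, window=DEFAULT_HBOND_WINDOW):
    """Independent oracle: enumerate all simple paths of length ≤ 4 in the
    hydrogen-bond graph over {ligand O, water O, carboxylate O} and apply
    the exclusion hierarchy."""
    roles = RoleMap.default()
    lig = roles.resolve_one(frame, "ligand_hydroxyl")
    ox = roles.resolve(frame, "carboxylate")
    waters = set(roles.resolve(frame, "water"))
    nodes = [lig, *ox, *waters]
    lo, hi = window
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, j in itertools.combinations(nodes, 2):
        d = float(np.linalg.norm(frame.coords[i] - frame.coords[j]))
        if lo <= d <= hi:
            g.add_edge(i, j)
    lengths = set()
    for o in ox:
        for path in nx.all_simple_paths(g, lig, o, cutoff=3):
            if all(p in waters for p in path[1:-1]):
                lengths.add(len(path))
    if 2 in lengths:
        return "direct"
    if 3 in lengths:
        return "water1"
    if 4 in lengths:
        return "water2"
    return "none"


class TestClassifyFrame:
    def test_direct(self):
        c = classify_frame(bridge_frame((0, 0, 2.7)))
        assert c.label == "direct" and len(c.path) == 2

    def test_direct_wins_over_coexisting_water_bridge(self):
        # ligand O in direct contact AND a valid one-water path: exclusion
        # hierarchy labels the frame direct
        frame = bridge_frame((0, 0, 2.7), [(0, 0, 5.45)])  # water H-bonds ligand O
        assert classify_frame(frame).label == "direct"

    def test_single_water_bridge(self):
        frame = bridge_frame((0, 0, 5.5), [(0, 0, 2.75)])
        c = classify_frame(frame)
        assert c.label == "water1"
        assert len(c.path) == 3
        assert frame.atoms[c.path[1]].resname == "HOH"

    def test_two_water_chain(self):
        frame = bridge_frame((0, 0, 8.25), [(0, 0, 5.5), (0, 0, 2.75)])
        c = classify_frame(frame)
        assert c.label == "water2"
        assert len(c.path) == 4
        assert len({c.path[1], c.path[2]}) == 2

    def test_no_engagement(self):
        frame = bridge_frame((0, 0, 6.0), [(6, 6, 3)])
        assert classify_frame(frame).label == "none"

    def test_three_water_chains_ignored(self):
        # ligand 11 Å out, three consecutive waters: beyond the scored orders
        frame = bridge_frame(
            (0, 0, 11.0), [(0, 0, 8.25), (0, 0, 5.5), (0, 0, 2.75)]
        )
        assert classify_frame(frame).label == "none"

    def test_water1_preferred_over_water2_when_both_exist(self):
        # one-water and two-water paths both present, no direct
        frame = bridge_frame(
            (0, 0, 5.5),
            [(0, 0, 2.75), (2.0, 0.2, 4.2), (2.1, 0.1, 1.9)],
        )
        assert oracle_label(frame) in {"water1"}  # construction sanity
        assert classify_frame(frame).label == "water1"

    def test_missing_role_fails(self):
        frame = make_frame(asp_carboxylate())
        with pytest.raises(Exception, match="ligand_hydroxyl"):
            classify_frame(frame)

    def test_matches_path_enumeration_oracle(self, rng):
        """Graph-search classification ≡ brute-force simple-path enumeration
        on random frames with ≤ 30 waters."""
        labels_seen = set()
        for _ in range(120):
            n_w = int(rng.integers(0, 30))
            # cluster waters near the ligand-aspartate axis so all classes occur
            waters_xyz = rng.uniform([-2, -2, 0], [4, 4, 9], size=(n_w, 3))
            lig_z = rng.uniform(2.2, 9.0)
            frame = bridge_frame((0, 0, lig_z), waters_xyz)
            got = classify_frame(frame).label
            assert got == oracle_label(frame)
            labels_seen.add(got)
        assert labels_seen == set(CLASSES)  # the sweep exercises all classes

    def test_invariant_under_water_reordering(self, rng):
        waters_xyz = [(0, 0, 2.75), (1.5, 1.5, 4.0), (6, 6, 3), (0.5, -0.5, 5.0)]
        base = classify_frame(bridge_frame((0, 0, 5.5), waters_xyz)).label
        for _ in range(5):
            perm = rng.permutation(len(waters_xyz))
            shuffled = [waters_xyz[i] for i in perm]
            assert classify_frame(bridge_frame((0, 0, 5.5), shuffled)).label == base

    def test_exclusion_hierarchy_monotonicity(self):
        # adding a direct contact flips a water1 frame to direct, never to none
        w1 = bridge_frame((0, 0, 5.5), [(0, 0, 2.75)])
        assert classify_frame(w1).label == "water1"
        direct = bridge_frame((0, 0, 2.7), [(0, 0, 5.45)])
        assert classify_frame(direct).label == "direct"
        # removing all waters from a water1 frame yields none
        stripped = bridge_frame((0, 0, 5.5))
        assert classify_frame(stripped).label == "none"


class TestBridgeFrequencies:
    def test_counting(self):
        labels = ["direct"] * 4 + ["water1"] * 3 + ["water2"] + ["none"] * 2
        table = bridge_frequencies({"rep1": labels})
        row = table.per_replicate.loc["rep1"]
        assert row.tolist() == [0.4, 0.3, 0.1, 0.2]

    def test_fractions_sum_to_one(self, rng):
        for _ in range(10):
            labels = list(rng.choice(CLASSES, size=int(rng.integers(1, 50))))
            table = bridge_frequencies({"r1": labels, "r2": labels[::-1]})
            np.testing.assert_allclose(
                table.per_replicate.sum(axis=1), 1.0, atol=1e-12
            )

    def test_identical_replicates_have_zero_sem(self):
        labels = ["direct", "water1", "none", "none"]
        table = bridge_frequencies({"r1": labels, "r2": list(labels)})
        assert (table.summary["sem"] == 0).all()

    def test_sem_closed_form(self):
        # replicate water1 fractions {0.2, 0.4}: mean 0.3, SEM 0.1
        table = bridge_frequencies(
            {"r1": ["water1", "none", "none", "none", "none"],
             "r2": ["water1", "water1", "none", "none", "none"]}
        )
        assert table.summary.loc["water1", "mean"] == pytest.approx(0.3)
        assert table.summary.loc["water1", "sem"] == pytest.approx(0.1)

    def test_empty_replicate_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            bridge_frequencies({"r1": []})

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            bridge_frequencies({"r1": ["direct", "bogus"]})


class TestCompareFrequencies:
    def test_identical_groups_p_one(self):
        res = compare_frequencies([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        res = compare_frequencies([0.1, 0.2], [0.8, 0.9])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact-enumeration"

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(2, 7)))
            b = rng.normal(size=int(rng.integers(2, 7)))
            res = compare_frequencies(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.u_statistic == pytest.approx(float(ref.statistic))
            assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_matches_full_enumeration_oracle_with_ties(self, rng):
        """Exact p equals an independently coded enumeration for n ≤ 6,
        including tied values."""
        for _ in range(10):
            a = rng.choice([0.1, 0.2, 0.3], size=3)
            b = rng.choice([0.1, 0.2, 0.3, 0.4], size=3)
            res = compare_frequencies(a, b)
            pooled = np.concatenate([a, b])
            u_obs = sum(
                1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
            )
            dist = []
            for pick in itertools.combinations(range(6), 3):
                rest = [k for k in range(6) if k not in pick]
                dist.append(
                    sum(
                        1.0 if pooled[i] > pooled[j] else
                        0.5 if pooled[i] == pooled[j] else 0.0
                        for i in pick for j in rest
                    )
                )
            dist = np.asarray(dist)
            p = min(1.0, 2 * min(np.mean(dist <= u_obs), np.mean(dist >= u_obs)))
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_large_groups_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 12)
        res = compare_frequencies(a, b)
        assert res.method == "normal-approx"
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_frequencies([0.3], [0.4, 0.5])


class TestFrameFractions:
    def test_stacking_frequency_designed_mixture(self):
        stacked = ring_frame(center_b=(0, 0, 3.8))
        apart = ring_frame(center_b=(0, 0, 6.0))
        summary = stacking_frequency(
            {"r1": [stacked] * 4, "r2": [apart] * 4, "r3": [stacked, apart] * 2}
        )
        assert summary.per_replicate.tolist() == [1.0, 0.0, 0.5]
        assert summary.mean == pytest.approx(0.5)

    def test_hbond_frequency_alternating_frames(self):
        def tq_frame(d):
            return make_frame(
                [
                    ("OH", "TYR", 326, "A", "O", (0, 0, 0)),
                    ("OE1", "GLN", 124, "A", "O", (0, 0, d)),
                ]
            )

        bonded, apart = tq_frame(2.8), tq_frame(4.0)
        summary = hbond_frequency(
            {"r1": [bonded, apart, bonded, apart]},
            "tyrosine_hydroxyl",
            "glutamine_amide",
        )
        assert summary.per_replicate.tolist() == [0.5]

    def test_hbond_frequency_extremes(self):
        frame = make_frame(
            [
                ("OH", "TYR", 326, "A", "O", (0, 0, 0)),
                ("OE1", "GLN", 124, "A", "O", (0, 0, 2.8)),
            ]
        )
        all_bonded = hbond_frequency(
            {"r": [frame] * 3}, "tyrosine_hydroxyl", "glutamine_amide"
        )
        assert all_bonded.mean == 1.0
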