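from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gxephos import curate_annotations, generate_kinase_annotations, ksea_matrix
from gxephos.ksea import ksea_sample, running_sum_score


# ---------------------------------------------------------------------------
# curation

def _edges(rows):
    return pd.DataFrame(rows, columns=["kinase", "substrate", "in_vivo",
                                       "substrate_protein"])


def test_promiscuous_site_removed():
    rows = [(f"K{i}", "siteX", True, "protX") for i in range(4)]
    rows += [("K1", "siteY", True, "protY")]
    cur = curate_annotations(_edges(rows))
    assert "siteX" in cur.removed_promiscuous
    assert all("siteX" not in s for s in cur.substrates.values())
    assert "siteY" in cur.substrates["K1"]


def test_three_kinases_keep_site():
    rows = [(f"K{i}", "siteX", True, "protX") for i in range(3)]
    cur = curate_annotations(_edges(rows))
    assert all("siteX" in s for s in cur.substrates.values())


def test_isoforms_merged():
    rows = [("Akt1", "s1", True, "p1"), ("Akt2", "s2", True, "p2")]
    cur = curate_annotations(_edges(rows), alias={"Akt1": "Akt", "Akt2": "Akt"})
    assert set(cur.substrates) == {"Akt"}
    assert cur.substrates["Akt"] == {"s1", "s2"}


def test_alias_cycle_rejected():
    with pytest.raises(ValueError, match="cycle"):
        curate_annotations(_edges([("A", "s", True, "p")]),
                           alias={"A": "B", "B": "A"})


def test_autophosphorylation_removed():
    rows = [("KinA", "site_on_KinA", True, "KinA"), ("KinA", "s2", True, "other")]
    cur = curate_annotations(_edges(rows))
    assert cur.substrates["KinA"] == {"s2"}
    assert cur.removed_autophosphorylation == ["site_on_KinA"]


def test_in_vitro_edges_dropped_and_supplement_added():
    rows = [("K", "s1", True, "p"), ("K", "s2", False, "p")]
    cur = curate_annotations(_edges(rows), supplement={"GSK3": {"g1", "g2"}})
    assert cur.substrates["K"] == {"s1"}
    assert cur.substrates["GSK3"] == {"g1", "g2"}


# ---------------------------------------------------------------------------
# running-sum statistic

def test_top_concentration_is_maximal_and_floor_p():
    rng = np.random.default_rng(0)
    values = pd.Series(
        np.sort(rng.normal(size=40))[::-1], index=[f"p{i:02d}" for i in range(40)]
    )
    substrates = list(values.index[:5])  # occupy the top ranks
    score, p, s = ksea_sample(values, substrates, n_perm=1000, rng=1)
    assert s == 5
    assert score == pytest.approx(1.0)
    assert p == pytest.approx(1 / 1001)


def test_uniformly_spread_substrates_score_small():
    ps = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        values = pd.Series(rng.normal(size=60), index=[f"p{i:02d}" for i in range(60)])
        ranked = values.sort_values(ascending=False).index
        substrates = list(ranked[::12])  # every 12th quantile
        score, p, _ = ksea_sample(values, substrates, n_perm=500, rng=seed)
        ps.append(p)
        assert abs(score) < 0.5
    assert np.mean(ps) > 0.5


def test_empirical_p_matches_exhaustive_enumeration():
    """N=8, |S|=3: the permutation p must match the exact tail probability of
    the fully enumerated null within binomial error."""
    n, s, n_perm = 8, 3, 1000
    values = pd.Series(
        [7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
        index=[f"p{i}" for i in range(n)],
    )
    all_scores = np.array(
        [
            float(running_sum_score(np.array(sorted(pos)) + 1, n, s))
            for pos in combinations(range(n), s)
        ]
    )
    for pick in [(0, 1, 2), (0, 3, 7), (2, 4, 6), (5, 6, 7)]:
        substrates = [f"p{i}" for i in pick]
        obs, p_emp, _ = ksea_sample(values, substrates, n_perm=n_perm, rng=123)
        exact = float(np.mean(np.abs(all_scores) >= abs(obs) - 1e-12))
        tol = 4 * np.sqrt(exact * (1 - exact) / n_perm) + 2 / (n_perm + 1)
        assert abs(p_emp - exact) <= tol


def test_score_antisymmetry():
    rng = np.random.default_rng(5)
    values = pd.Series(rng.normal(size=50), index=[f"p{i:02d}" for i in range(50)])
    subs = list(values.index[::7])
    s1, _, _ = ksea_sample(values, subs, n_perm=10, rng=0)
    s2, _, _ = ksea_sample(-values, subs, n_perm=10, rng=0)
    assert s1 == pytest.approx(-s2, abs=1e-12)


def test_seed_determinism(processed):
    from gxephos import insulin_response

    _, tab, meta, truth, reg = processed
    resp = insulin_response(tab, meta)
    ann = generate_kinase_annotations(truth, n_kinases=4, substrates_per_kinase=8,
                                      seed=1)
    cur = curate_annotations(ann.edges, alias=ann.alias)
    a = ksea_matrix(resp, meta, cur, n_perm=200, seed=9)
    b = ksea_matrix(resp, meta, cur, n_perm=200, seed=9)
    pd.testing.assert_frame_equal(a.scores, b.scores)
    pd.testing.assert_frame_equal(a.pvalues, b.pvalues)


def test_small_substrate_sets_excluded_and_empty_map(two_by_two_meta):
    meta = two_by_two_meta
    rng = np.random.default_rng(2)
    ins = meta.select(treatment="insulin")
    resp = pd.DataFrame(rng.normal(size=(30, len(ins))),
                        index=[f"p{i}" for i in range(30)], columns=ins)
    from gxephos.ksea import KinaseSubstrateMap

    four = KinaseSubstrateMap(substrates={"K4": set(resp.index[:4])})
    out = ksea_matrix(resp, meta, four, n_perm=50, seed=0)
    assert out.pvalues.loc["K4"].isna().all()
    empty = ksea_matrix(resp, meta, KinaseSubstrateMap(substrates={}), n_perm=50,
                        seed=0)
    assert empty.scores.empty and empty.qualifying == []


def test_planted_signal_kinase_qualifies(processed):
    from gxephos import insulin_response

    _, tab, meta, truth, reg = processed
    resp = insulin_response(tab, meta)
    ann = generate_kinase_annotations(truth, n_kinases=8, substrates_per_kinase=12,
                                      seed=5)
    cur = curate_annotations(ann.edges, alias=ann.alias)
    scores = ksea_matrix(resp, meta, cur, n_perm=500, seed=7)
    assert set(ann.signal_kinases) <= set(scores.qualifying)
    for k in ann.signal_kinases:
        assert (scores.scores.loc[k].dropna() > 0).all()
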