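import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxephos import (
    build_modules,
    eigenpeptide_trait_correlation,
    pca_fold_changes,
    term_enrichment,
    topological_overlap,
)


def _blocks(rng, sizes, n_samp=60, r=0.9, n_noise=40):
    rows = []
    for size in sizes:
        f = rng.normal(0, 1, n_samp)
        lam = np.sqrt(r)
        for _ in range(size):
            rows.append(lam * f + np.sqrt(1 - lam**2) * rng.normal(0, 1, n_samp))
    rows.extend(rng.normal(0, 1, (n_noise, n_samp)))
    X = np.vstack(rows)
    return pd.DataFrame(
        X, index=[f"p{i:03d}" for i in range(X.shape[0])],
        columns=[f"s{j}" for j in range(n_samp)],
    )


# ---------------------------------------------------------------------------
# TOM

def test_tom_symmetry_range_and_diagonal():
    rng = np.random.default_rng(0)
    r = rng.uniform(-1, 1, size=(20, 20))
    adj = np.abs((r + r.T) / 2) ** 3
    np.fill_diagonal(adj, 1.0)
    tom = topological_overlap(adj)
    assert np.allclose(tom, tom.T)
    assert (tom >= 0).all() and (tom <= 1).all()
    assert np.allclose(np.diag(tom), 1.0)


def test_tom_isolated_perfect_pair():
    adj = np.zeros((4, 4))
    adj[0, 1] = adj[1, 0] = 1.0
    tom = topological_overlap(adj)
    assert tom[0, 1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# module detection

def test_two_planted_blocks_recovered():
    rng = np.random.default_rng(1)
    resp = _blocks(rng, [20, 20])
    model = build_modules(resp)
    lab = model.labels
    assert len(model.modules) == 2
    m1 = lab.iloc[:20].mode()[0]
    m2 = lab.iloc[20:40].mode()[0]
    assert m1 != 0 and m2 != 0 and m1 != m2
    acc = ((lab.iloc[:20] == m1).sum() + (lab.iloc[20:40] == m2).sum()) / 40
    assert acc >= 0.95


def test_subthreshold_block_unassigned():
    rng = np.random.default_rng(2)
    resp = _blocks(rng, [20, 10])
    model = build_modules(resp, min_module_size=15)
    assert (model.labels.iloc[20:30] == 0).all()


def test_constant_rows_excluded():
    rng = np.random.default_rng(3)
    resp = _blocks(rng, [20, 20])
    resp.iloc[5] = 1.0  # constant peptide
    model = build_modules(resp)
    assert model.labels.iloc[5] == 0


def test_eigenpeptide_orientation_and_kme():
    rng = np.random.default_rng(4)
    resp = _blocks(rng, [20, 20])
    model = build_modules(resp)
    for m in model.modules:
        members = model.members(m)
        mean_profile = resp.loc[members].sub(
            resp.loc[members].mean(axis=1), axis=0
        ).mean(axis=0)
        e = model.eigenpeptides.loc[m]
        assert np.corrcoef(e, mean_profile)[0, 1] >= 0
        # members have higher own-module kME than the non-member median
        own = model.kme.loc[members, m]
        others = model.kme.loc[model.labels.index.difference(members), m]
        assert own.median() > others.abs().median()


def test_merge_idempotence():
    from gxephos.subnetworks import _merge_modules, _standardise

    rng = np.random.default_rng(5)
    resp = _blocks(rng, [20, 20])
    Z = pd.DataFrame(_standardise(resp.to_numpy()), index=resp.index,
                     columns=resp.columns)
    labels = pd.Series([1] * 20 + [2] * 20 + [0] * 40, index=resp.index)
    l1, _ = _merge_modules(Z, labels[labels != 0], 0.25)
    l2, _ = _merge_modules(Z, l1, 0.25)
    pd.testing.assert_series_equal(l1, l2)


def test_near_identical_modules_merge():
    rng = np.random.default_rng(6)
    n_samp = 60
    f = rng.normal(0, 1, n_samp)
    rows = [0.97 * f + 0.24 * rng.normal(0, 1, n_samp) for _ in range(40)]
    rows += list(rng.normal(0, 1, (30, n_samp)))
    resp = pd.DataFrame(np.vstack(rows), index=[f"p{i}" for i in range(70)],
                        columns=[f"s{j}" for j in range(n_samp)])
    model = build_modules(resp, min_module_size=15)
    # one underlying factor: never more than one module survives merging
    assert len(model.modules) == 1


# ---------------------------------------------------------------------------
# trait correlation

def test_trait_equals_eigenpeptide_gives_r_one():
    rng = np.random.default_rng(7)
    resp = _blocks(rng, [20, 20])
    model = build_modules(resp)
    m = model.modules[0]
    out = eigenpeptide_trait_correlation(model, model.eigenpeptides.loc[m])
    assert out.loc[m, "r"] == pytest.approx(1.0)


def test_independent_trait_rarely_correlates():
    hits = 0
    total = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        resp = _blocks(rng, [20, 20], n_samp=50)
        model = build_modules(resp)
        trait = pd.Series(rng.normal(size=50), index=resp.columns)
        out = eigenpeptide_trait_correlation(model, trait)
        total += len(out)
        hits += int((out["r"].abs() > 0.35).sum())
    assert hits / total <= 0.1


def test_driver_module_has_largest_correlation():
    from gxephos import generate_phenotype

    rng = np.random.default_rng(8)
    resp = _blocks(rng, [20, 20])
    model = build_modules(resp)
    drivers = list(resp.index[:20])
    trait = generate_phenotype(resp, drivers, r_target=0.8, seed=0)
    out = eigenpeptide_trait_correlation(model, trait)
    m_driver = model.labels.iloc[:20].mode()[0]
    assert out["r"].abs().idxmax() == m_driver


# ---------------------------------------------------------------------------
# enrichment

def _hypergeom_tail(overlap, fg, term, bg):
    """Direct summation oracle for the one-sided Fisher p."""
    return float(
        sum(
            stats.hypergeom.pmf(k, bg, term, fg)
            for k in range(overlap, min(fg, term) + 1)
        )
    )


def test_fisher_matches_hypergeometric_summation():
    bg = [f"g{i}" for i in range(100)]
    fg = bg[:10]
    terms = {"T": set(bg[7:20])}  # overlap 3 (g7, g8, g9)
    out = term_enrichment(fg, bg, terms)
    p_oracle = _hypergeom_tail(3, 10, 13, 100)
    assert out.loc[0, "p"] == pytest.approx(p_oracle, abs=1e-12)


def test_small_overlap_not_tested():
    bg = [f"g{i}" for i in range(50)]
    out = term_enrichment(bg[:10], bg, {"T": set(bg[8:12])})  # overlap 2
    assert out.empty


def test_foreground_equals_background_fold_one():
    bg = [f"g{i}" for i in range(40)]
    out = term_enrichment(bg, bg, {"T": set(bg[:10])})
    assert out.loc[0, "fold_enrichment"] == pytest.approx(1.0)


def test_empty_background_rejected():
    with pytest.raises(ValueError):
        term_enrichment([], [], {"T": {"a"}})


# ---------------------------------------------------------------------------
# PCA of fold changes

def test_rank_one_input_single_component():
    u = np.arange(1, 11, dtype=float)
    v = np.array([1.0, -2.0, 0.5, 3.0])
    lfc = pd.DataFrame(np.outer(u, v), columns=[f"c{j}" for j in range(4)])
    scores, var = pca_fold_changes(lfc)
    assert var[0] == pytest.approx(100.0)


def test_variance_explained_sums_to_hundred():
    rng = np.random.default_rng(9)
    lfc = pd.DataFrame(rng.normal(size=(50, 10)),
                       columns=[f"c{j}" for j in range(10)])
    _, var = pca_fold_changes(lfc)
    assert np.sum(var) == pytest.approx(100.0)


def test_two_factor_structure_in_leading_components():
    rng = np.random.default_rng(10)
    f1 = rng.normal(size=10)
    f2 = rng.normal(size=10)
    a = rng.normal(size=200)
    b = rng.normal(size=200)
    lfc = pd.DataFrame(
        np.outer(a, f1) + np.outer(b, f2) + rng.normal(0, 0.05, size=(200, 10)),
        columns=[f"c{j}" for j in range(10)],
    )
    _, var = pca_fold_changes(lfc)
    assert var[0] + var[1] > 95.0
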