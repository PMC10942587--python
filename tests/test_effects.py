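import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxephos import PhosphoTable, gate_f, gate_g, insulin_response, outside_gate
from gxephos.data import combo_label
from gxephos.effects import (
    GATE_BASE,
    diet_effects,
    entity_anova,
    strain_effects,
)

C = GATE_BASE


# ---------------------------------------------------------------------------
# gate functions

def test_gate_values_at_named_points():
    assert gate_f(0.0) == pytest.approx(C / 2)
    assert gate_g(0.0) == pytest.approx(-C / 2)
    assert gate_f(2 * C) == pytest.approx(3 * C)


@pytest.mark.parametrize("knot", [2 * C, 0.0, -C / 2, -3 * C])
def test_gate_f_continuous_at_knots(knot):
    eps = 1e-9
    assert gate_f(knot - eps) == pytest.approx(gate_f(knot + eps), abs=1e-6)


def test_gate_antisymmetry_on_grid():
    x = np.linspace(-3, 3, 1000)
    assert np.max(np.abs(gate_g(x) + gate_f(-x))) < 1e-12


def test_printed_g_variant_is_discontinuous():
    """The alternative printed lower bound jumps at both knots of its second
    piece; the default (antisymmetric) form is the analysis gate."""
    eps = 1e-9
    lo = gate_g(C / 2 - eps, printed_g_variant=True)
    hi = gate_g(C / 2 + eps, printed_g_variant=True)
    assert abs(hi - lo) > 0.2


@settings(max_examples=200, derandomize=True)
@given(st.floats(min_value=-10, max_value=10))
def test_gate_margin_property(x):
    f, g = float(gate_f(x)), float(gate_g(x))
    assert g < x < f
    assert C / 2 - 1e-12 <= f - x <= C + 1e-12
    assert C / 2 - 1e-12 <= x - g <= C + 1e-12


def test_equal_lfcs_never_pass_gate():
    x = np.linspace(-4, 4, 101)
    assert not outside_gate(x, x).any()


# ---------------------------------------------------------------------------
# insulin responses

def test_response_subtracts_unstimulated_median(two_by_two_meta):
    meta = two_by_two_meta
    vals = {}
    for _, r in meta.frame.iterrows():
        if r["treatment"] == "unstimulated":
            vals[r["sample_id"]] = {1: 10.0, 2: 11.0, 3: 12.0}[r["replicate"]]
        else:
            vals[r["sample_id"]] = 12.0
    table = PhosphoTable(pd.DataFrame([vals], index=["p"]))
    resp = insulin_response(table, meta)
    assert np.allclose(resp.loc["p"].dropna(), 1.0)
    assert set(resp.columns) == set(meta.select(treatment="insulin"))


def test_response_shift_invariance(two_by_two_meta):
    meta = two_by_two_meta
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.normal(15, 1, size=(4, len(meta.sample_ids))),
        index=list("abcd"), columns=meta.sample_ids,
    )
    shifted = vals.copy()
    shifted[meta.select(strain="A", diet="CHOW")] += 3.0
    r1 = insulin_response(PhosphoTable(vals), meta)
    r2 = insulin_response(PhosphoTable(shifted), meta)
    pd.testing.assert_frame_equal(r1, r2)


def test_response_missing_without_unstimulated(two_by_two_meta):
    meta = two_by_two_meta
    vals = pd.DataFrame(
        10.0, index=["p"], columns=meta.sample_ids
    )
    vals[meta.select(strain="A", diet="CHOW", treatment="unstimulated")] = np.nan
    resp = insulin_response(PhosphoTable(vals), meta)
    a_chow = meta.select(strain="A", diet="CHOW", treatment="insulin")
    assert resp.loc["p", a_chow].isna().all()
    assert resp.loc["p"].drop(a_chow).notna().all()


# ---------------------------------------------------------------------------
# cascades on constructed responses

def _five_strain_meta(n=6):
    rows = []
    for strain in ("C57Bl6J", "NOD", "BXH9", "CAST", "BXD34"):
        for diet in ("CHOW", "HFD"):
            for treat in ("unstimulated", "insulin"):
                for rep in range(1, n + 1):
                    rows.append(
                        dict(sample_id=f"{strain}_{diet}_{treat}_{rep}",
                             strain=strain, diet=diet, treatment=treat,
                             replicate=rep)
                    )
    from gxephos import SampleMeta

    return SampleMeta(pd.DataFrame(rows))


def _make_responses(meta, effect_fn, n_pep=40, sd=0.2, seed=0):
    """Responses (and matching lfc table) for peptides with per-(strain,diet)
    mean effects given by effect_fn(i, strain, diet)."""
    rng = np.random.default_rng(seed)
    ins = meta.select(treatment="insulin")
    info = meta.frame.set_index("sample_id")
    resp = pd.DataFrame(index=[f"p{i}" for i in range(n_pep)], columns=ins,
                        dtype=float)
    lfc = {}
    for i in range(n_pep):
        for combo in meta.combos:
            strain, diet = combo.split("|")
            lfc.setdefault(combo, []).append(effect_fn(i, strain, diet))
        for c in ins:
            mu = effect_fn(i, info.loc[c, "strain"], info.loc[c, "diet"])
            resp.loc[f"p{i}", c] = mu + rng.normal(0, sd)
    return resp, pd.DataFrame(lfc, index=resp.index)


def test_strain_effect_weaker_strain_detected():
    meta = _five_strain_meta()

    def eff(i, strain, diet):
        if i < 10 and strain == "CAST":
            return 0.0  # planted: CAST loses the response entirely
        return 2.0

    resp, lfc = _make_responses(meta, eff)
    out = strain_effects(resp, lfc, meta)
    planted = out.iloc[:10]
    assert (planted["strain:CAST"] == "weaker").mean() >= 0.9
    assert planted["strain_effect"].mean() >= 0.9
    untouched = out.iloc[10:]
    assert (untouched["strain_effect"]).mean() <= 0.1


def test_identical_strains_no_effect():
    meta = _five_strain_meta()
    resp, lfc = _make_responses(meta, lambda i, s, d: 1.5)
    out = strain_effects(resp, lfc, meta)
    assert not out["strain_effect"].any()


def test_gate_blocks_equal_lfc_even_with_tiny_p():
    """A strain with identical fold change to the reference can never be
    called, because f(x) > x > g(x) strictly."""
    meta = _five_strain_meta()
    rng = np.random.default_rng(3)
    # responses differ in variance only -> possible small t-test p by chance,
    # but lfc identical
    resp, lfc = _make_responses(meta, lambda i, s, d: 2.0, sd=0.3, seed=3)
    out = strain_effects(resp, lfc, meta)
    assert not out["strain_effect"].any()


def test_interaction_classified_with_correct_strain():
    meta = _five_strain_meta()

    def eff(i, strain, diet):
        if i < 10 and strain == "NOD" and diet == "HFD":
            return 0.0  # planted interaction: NOD loses its HFD response
        return 2.0

    resp, lfc = _make_responses(meta, eff)
    out = diet_effects(resp, lfc, meta)
    planted = out.iloc[:10]
    assert (planted["diet_class"] == "strainxdiet").mean() >= 0.9
    assert (planted["diet:NOD"] == "weaker").mean() >= 0.9


def test_uniform_diet_effect_on_iid_responses():
    meta = _five_strain_meta()

    def eff(i, strain, diet):
        base = 2.0
        if i < 10 and diet == "HFD":
            return base - 1.0  # all strains attenuated equally
        return base

    resp, lfc = _make_responses(meta, eff)
    out = diet_effects(resp, lfc, meta)
    planted = out.iloc[:10]
    assert (planted["diet_class"] == "uniform").mean() >= 0.8
    assert (out.iloc[10:]["diet_class"] == "none").mean() >= 0.9


def test_neither_term_significant_gives_none():
    meta = _five_strain_meta()
    resp, lfc = _make_responses(meta, lambda i, s, d: 1.0, sd=0.25, seed=9)
    out = diet_effects(resp, lfc, meta)
    assert (out["diet_class"] == "none").mean() >= 0.95


def test_strain_call_ignores_hfd_rows(processed):
    """Shuffling HFD responses leaves strain-effect calls unchanged."""
    _, tab, meta, _, reg = processed
    ids = reg.regulated_ids[:40]
    resp = insulin_response(tab, meta, ids)
    lfc = reg.lfc.loc[ids]
    out1 = strain_effects(resp, lfc, meta)
    rng = np.random.default_rng(0)
    shuffled = resp.copy()
    hfd_cols = [c for c in resp.columns if c in meta.select(diet="HFD")]
    shuffled[hfd_cols] = resp[hfd_cols].sample(frac=1.0, random_state=1).to_numpy()
    out2 = strain_effects(shuffled, lfc, meta)
    pd.testing.assert_frame_equal(out1, out2)


# ---------------------------------------------------------------------------
# entity-level ANOVAs

def test_entity_anova_detects_shifted_strain():
    meta = _five_strain_meta()
    ins = meta.select(treatment="insulin")
    rng = np.random.default_rng(1)
    info = meta.frame.set_index("sample_id")
    rows = []
    for k in range(10):
        base = rng.normal(0, 0.1, size=len(ins))
        if k == 0:
            base += np.array(
                [1.0 if info.loc[c, "strain"] == "CAST" else 0.0 for c in ins]
            )
        rows.append(base)
    scores = pd.DataFrame(rows, index=[f"k{k}" for k in range(10)], columns=ins)
    res = entity_anova(scores, meta, design="strain-on-CHOW")
    assert res.loc["k0", "p_adj"] < 0.05
    assert (res.drop("k0")["p_adj"] > 0.05).all()


def test_entity_anova_two_way_design():
    meta = _five_strain_meta()
    ins = meta.select(treatment="insulin")
    info = meta.frame.set_index("sample_id")
    rng = np.random.default_rng(2)
    diet_shift = np.array([0.8 if info.loc[c, "diet"] == "HFD" else 0.0 for c in ins])
    scores = pd.DataFrame(
        [rng.normal(0, 0.1, len(ins)) + diet_shift,
         rng.normal(0, 0.1, len(ins))],
        index=["diet_kinase", "null_kinase"], columns=ins,
    )
    res = entity_anova(scores, meta, design="strainxdiet")
    assert res.loc["diet_kinase", "diet_p_adj"] < 0.05
    assert res.loc["null_kinase", "diet_p_adj"] > 0.05
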