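"""Generators: determinism, planted-label conservation, design counts."""

import math

import numpy as np
import pandas as pd
import pytest

import kinovuln as kv
from kinovuln.synthetic import JointSimParams, generate_joint_study


def test_expression_matches_discovery_design():
    study, truth = kv.generate_expression(kv.ExpressionSimParams(seed=7))
    assert study.values.shape[1] == 16 + 3  # 16 tumors vs 3 normal cerebella
    assert (study.groups == "tumor").sum() == 16
    assert (study.groups == "normal").sum() == 3


def test_expression_seed_determinism_and_labels():
    p = kv.ExpressionSimParams(n_genes=200, frac_overexpressed=0.1, seed=7)
    s1, t1 = kv.generate_expression(p)
    s2, t2 = kv.generate_expression(p)
    pd.testing.assert_frame_equal(s1.values, s2.values)
    pd.testing.assert_frame_equal(t1, t2)
    assert t1["planted"].sum() == 20  # label conservation
    # planted genes really carry the shift, unplanted do not
    assert (t1.loc[t1["planted"], "true_log2fc"] != 0).all()
    assert (t1.loc[~t1["planted"], "true_log2fc"] == 0).all()


@pytest.mark.parametrize("bad", [
    dict(n_genes=0), dict(n_tumor=0), dict(frac_overexpressed=1.5),
    dict(noise_sd=-1.0),
])
def test_expression_param_validation(bad):
    with pytest.raises(ValueError):
        kv.generate_expression(kv.ExpressionSimParams(**bad))


def test_screen_library_structure():
    wells, truth = kv.generate_screen(kv.ScreenSimParams(seed=0))
    samples = wells[wells["role"] == "sample"]
    assert len(samples) == 710 * 3 == 2130
    assert wells["plate_id"].nunique() == math.ceil(2130 / 80) == 27
    assert samples["sirna_id"].is_unique
    # every plate carries its control triplicate
    per_plate_controls = wells[wells["role"] == "control"].groupby("plate_id").size()
    assert (per_plate_controls == 3).all()
    assert wells.loc[wells["role"] == "control", "gene"].isna().all()
    assert len(truth) == 710


def test_screen_seed_determinism(small_screen_params):
    w1, _ = kv.generate_screen(small_screen_params)
    w2, _ = kv.generate_screen(small_screen_params)
    pd.testing.assert_frame_equal(w1, w2)


def test_screen_essential_gene_lowers_absorbance(small_screen_params):
    gene = small_screen_params.gene_ids[0]
    p_null = small_screen_params
    p_hit = kv.ScreenSimParams(**{**p_null.__dict__,
                                  "essential_genes": {gene: 0.6}})
    null_wells, _ = kv.generate_screen(p_null)
    hit_wells, _ = kv.generate_screen(p_hit)
    m_null = null_wells.loc[null_wells["gene"] == gene, "absorbance"].mean()
    m_hit = hit_wells.loc[hit_wells["gene"] == gene, "absorbance"].mean()
    assert m_hit < 0.6 * m_null


def test_screen_rejects_unknown_essential_gene(small_screen_params):
    params = kv.ScreenSimParams(**{**small_screen_params.__dict__,
                                   "essential_genes": {"NOPE": 0.5}})
    with pytest.raises(ValueError, match="NOPE"):
        kv.generate_screen(params)


def test_screen_rejects_bad_layout():
    with pytest.raises(ValueError):
        kv.ScreenSimParams(sample_wells_per_plate=0).validate()
    with pytest.raises(ValueError):
        kv.ScreenSimParams(sample_wells_per_plate=95, controls_per_plate=3).validate()


def test_dose_response_noiseless_on_curve():
    p = kv.DoseSimParams(noise_sd=0.0, true_ic50=150.0, true_hill=1.2)
    table = kv.generate_dose_response(p)
    expected = kv.four_pl(table["dose_nM"], 0.0, 100.0, 150.0, 1.2)
    np.testing.assert_allclose(table["viability_pct"], expected, rtol=1e-12)
    pd.testing.assert_frame_equal(table, kv.generate_dose_response(p))


def test_dose_response_rejects_empty_and_unsorted_doses():
    with pytest.raises(ValueError):
        kv.generate_dose_response(kv.DoseSimParams(doses=()))
    with pytest.raises(ValueError):
        kv.generate_dose_response(kv.DoseSimParams(doses=(10.0, 5.0)))


def test_combination_independence_and_determinism():
    p = kv.ComboSimParams(excess=0.0, noise_sd=0.0, seed=5)
    combo = kv.generate_combination(p)
    fit_a = kv.FourPLFit(*p.fit_a, rss=0.0, converged=True)
    fit_b = kv.FourPLFit(*p.fit_b, rss=0.0, converged=True)
    matrix = kv.bliss_excess(combo, fit_a, fit_b)
    np.testing.assert_allclose(matrix.grid["excess"], 0.0, atol=1e-12)
    pd.testing.assert_frame_equal(combo, kv.generate_combination(p))


def test_combination_rejects_excess_outside_unit_band():
    with pytest.raises(ValueError):
        kv.generate_combination(kv.ComboSimParams(excess=1.5))


def test_xenograft_noiseless_volumes_exactly_exponential():
    p = kv.XenoSimParams(n_per_arm=3, v0_cv=0.0, measurement_cv=0.0,
                         treatment_effect=0.5, seed=2)
    table = kv.add_volumes(kv.generate_xenograft(p))
    for (animal, arm), sub in table.groupby(["animal_id", "arm"]):
        rate = p.growth_rate * (p.treatment_effect if arm == "treated" else 1.0)
        expected = p.v0_mean * np.exp(rate * sub["day"].to_numpy())
        np.testing.assert_allclose(sub["volume_mm3"], expected, rtol=1e-9)


def test_xenograft_determinism_and_validation():
    p = kv.XenoSimParams(seed=9)
    pd.testing.assert_frame_equal(kv.generate_xenograft(p), kv.generate_xenograft(p))
    with pytest.raises(ValueError):
        kv.generate_xenograft(kv.XenoSimParams(v0_mean=-1.0))
    with pytest.raises(ValueError):
        kv.generate_xenograft(kv.XenoSimParams(treatment_effect=0.0))


def test_joint_study_truth_labels_consistent():
    params = JointSimParams(seed=4)
    study, wells, truth = generate_joint_study(params)
    assert truth["dual"].sum() == params.n_dual
    assert truth["overexpressed"].sum() == params.n_dual + params.n_overexpressed_only
    assert truth["essential"].sum() == params.n_dual + params.n_essential_only
    assert (truth.loc[truth["dual"], "overexpressed"]).all()
    assert (truth.loc[truth["dual"], "essential"]).all()
    assert set(study.genes) == set(truth["gene"])
    assert set(wells.loc[wells["role"] == "sample", "gene"]) == set(truth["gene"])
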