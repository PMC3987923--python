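"""Screen scoring: background, plate normalization, Z, aggregation, hits."""

import numpy as np
import pandas as pd
import pytest

import kinovuln as kv


def test_background_subtraction_clips_at_zero(tiny_wells):
    out = kv.subtract_background(tiny_wells, 0.05)
    np.testing.assert_allclose(out["absorbance"],
                               [0.75, 0.95, 1.15, 0.45, 1.45])
    low = tiny_wells.assign(absorbance=[0.03] * 5)
    assert (kv.subtract_background(low, 0.05)["absorbance"] == 0.0).all()
    pd.testing.assert_frame_equal(kv.subtract_background(tiny_wells, 0.0), tiny_wells)
    with pytest.raises(ValueError):
        kv.subtract_background(tiny_wells, -0.1)


def test_plate_normalization_to_control_mean(tiny_wells):
    out = kv.normalize_plates(tiny_wells)
    # control mean is (0.8+1.0+1.2)/3 = 1.0, so values pass through
    np.testing.assert_allclose(out["normalized"], tiny_wells["absorbance"])
    ctrl = out[out["role"] == "control"]
    assert ctrl["normalized"].mean() == pytest.approx(1.0)


def test_plate_normalization_is_scale_invariant(tiny_wells):
    doubled = tiny_wells.copy()
    doubled["plate_id"] = "P2"
    doubled["absorbance"] *= 2.0
    both = pd.concat([tiny_wells, doubled], ignore_index=True)
    out = kv.normalize_plates(both)
    p1 = out[out["plate_id"] == "P1"]["normalized"].to_numpy()
    p2 = out[out["plate_id"] == "P2"]["normalized"].to_numpy()
    np.testing.assert_allclose(p1, p2)


def test_plate_without_controls_rejected(tiny_wells):
    broken = tiny_wells.copy()
    broken["role"] = "sample"
    with pytest.raises(ValueError, match="no control"):
        kv.normalize_plates(broken)
    zeroed = tiny_wells.copy()
    zeroed.loc[zeroed["role"] == "control", "absorbance"] = 0.0
    with pytest.raises(ValueError, match="non-positive"):
        kv.normalize_plates(zeroed)


def test_z_formula_against_hand_value():
    # 10 sample wells with mean 1.0 and sd 0.2 (constructed), probe at 0.6
    vals = np.array([0.8, 1.2, 0.8, 1.2, 0.8, 1.2, 0.8, 1.2, 1.0, 1.0])
    vals = (vals - vals.mean()) / vals.std(ddof=1) * 0.2 + 1.0
    wells = pd.DataFrame({
        "plate_id": "P1", "well": [f"A{i + 1}" for i in range(10)] + ["B1"],
        "sirna_id": [f"s{i}" for i in range(11)],
        "gene": [f"G{i}" for i in range(10)] + ["GX"],
        "role": "sample",
        "normalized": list(vals) + [0.6],
    })
    # the probe well participates in the reference; exclude it by role
    wells.loc[10, "role"] = "control"
    out = kv.compute_z(wells)
    assert out.loc[10, "z"] == pytest.approx((0.6 - 1.0) / 0.2)
    assert out.loc[10, "z"] == pytest.approx(-2.0)


def test_z_is_invariant_to_affine_shift(tiny_wells):
    norm = kv.normalize_plates(tiny_wells)
    z1 = kv.compute_z(norm)["z"]
    shifted = norm.copy()
    shifted["normalized"] = shifted["normalized"] * 3.0 + 1.0
    z2 = kv.compute_z(shifted)["z"]
    np.testing.assert_allclose(z1, z2, atol=1e-12)


def test_z_reference_excludes_controls_and_needs_spread(tiny_wells):
    norm = kv.normalize_plates(tiny_wells)
    flat = norm.copy()
    flat.loc[flat["role"] == "sample", "normalized"] = 1.0
    with pytest.raises(ValueError):
        kv.compute_z(flat)


def test_per_plate_reference_standardizes_each_plate(small_screen_params):
    wells, _ = kv.generate_screen(small_screen_params)
    norm = kv.normalize_plates(kv.subtract_background(wells, 0.05))
    out = kv.compute_z(norm, reference="per_plate_samples")
    for _, sub in out[out["role"] == "sample"].groupby("plate_id"):
        assert sub["z"].mean() == pytest.approx(0.0, abs=1e-10)
        assert sub["z"].std(ddof=1) == pytest.approx(1.0, rel=1e-10)


def test_gene_aggregation_is_the_arithmetic_mean():
    wells = pd.DataFrame({
        "plate_id": "P1", "well": ["A1", "A2", "A3", "A4"],
        "sirna_id": ["a1", "a2", "a3", "b1"],
        "gene": ["A", "A", "A", "B"], "role": "sample",
        "z": [-2.5, -1.5, -2.0, 0.7],
    })
    scores = kv.aggregate_genes(wells).set_index("gene")
    assert scores.at["A", "mean_z"] == pytest.approx(-2.0)
    assert scores.at["B", "mean_z"] == pytest.approx(0.7)  # single-siRNA gene
    permuted = kv.aggregate_genes(wells.iloc[::-1].reset_index(drop=True))
    pd.testing.assert_series_equal(scores["mean_z"],
                                   permuted.set_index("gene")["mean_z"])


def test_hit_calling_uses_strict_inequalities():
    scores = pd.DataFrame({"gene": ["A", "B", "C", "D"],
                           "mean_z": [-2.0, -2.1, -3.5, -3.0]})
    hits, stringent = kv.call_hits(scores)
    assert hits == {"B", "C", "D"}       # -2.0 exactly is NOT a hit
    assert stringent == {"C"}            # -3.0 exactly is NOT stringent
    assert stringent <= hits
    assert kv.call_hits(scores.iloc[:0]) == (set(), set())
    with pytest.raises(ValueError):
        kv.call_hits(scores, threshold=-3.0, stringent=-2.0)


def test_plate_scale_change_leaves_all_z_unchanged(small_screen_params):
    wells, _ = kv.generate_screen(small_screen_params)
    scaled = wells.copy()
    one_plate = scaled["plate_id"] == scaled["plate_id"].iloc[0]
    scaled.loc[one_plate, "absorbance"] *= 3.0
    z1 = kv.compute_z(kv.normalize_plates(wells))["z"]
    z2 = kv.compute_z(kv.normalize_plates(scaled))["z"]
    np.testing.assert_allclose(z1, z2, atol=1e-12)


def test_planted_essential_genes_become_hits(small_screen_params):
    # in a 24-gene screen keep the planted fraction small so the pooled
    # sample-well reference is not dominated by the essential genes
    targets = small_screen_params.gene_ids[:2]
    params = kv.ScreenSimParams(**{**small_screen_params.__dict__,
                                   "essential_genes": {g: 0.6 for g in targets}})
    wells, _ = kv.generate_screen(params)
    _, _, hits, _ = kv.score_screen(wells, background=params.background)
    assert set(targets) <= hits


def test_robust_z_resists_outliers(small_screen_params):
    wells, _ = kv.generate_screen(small_screen_params)
    spiked = wells.copy()
    idx = spiked.index[spiked["role"] == "sample"][:3]
    spiked.loc[idx, "absorbance"] *= 10.0  # gross readout artifacts
    norm = kv.normalize_plates(kv.subtract_background(spiked, 0.05))
    plain = kv.compute_z(norm)
    robust = kv.compute_z(norm, robust=True)
    typical = norm["role"] == "sample"
    typical &= ~norm.index.isin(idx)
    assert robust.loc[typical, "z"].std() > plain.loc[typical, "z"].std()
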