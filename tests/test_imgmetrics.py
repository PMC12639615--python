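"""Tests of the thresholded-area ratio statistics and line profiles."""

import numpy as np
import pandas as pd
import pytest

from satb2quant import imgmetrics, synth


def _pair_from_masks(pmask, dmask):
    """Build a crisp two-level pair whose thresholded masks equal the
    given boolean patterns under any of the threshold methods."""
    protein = np.where(pmask, 0.9, 0.1)
    dna = np.where(dmask, 0.9, 0.1)
    # anchor min/max away from the two modes so they are interior bins
    for img in (protein, dna):
        img[0, 0], img[0, 1] = 0.0, 1.0
    return synth.ImagePair(protein=protein, dna=dna)


def test_identical_channels_give_unit_ratios(two_level_pair):
    m = imgmetrics.quantify_pair(two_level_pair)
    assert m.aggregation_ratio == pytest.approx(1.0)
    assert m.coloc_ratio == pytest.approx(1.0)
    assert m.nuclear_fraction == pytest.approx(1.0)


def test_half_area_protein_mask_gives_half_aggregation():
    dmask = np.zeros((64, 64), dtype=bool)
    dmask[10:50, 10:50] = True        # 1600 px
    pmask = np.zeros((64, 64), dtype=bool)
    pmask[10:30, 10:50] = True        # 800 px
    pair = _pair_from_masks(pmask, dmask)
    assert imgmetrics.aggregation_ratio(pair) == pytest.approx(0.5, abs=0.02)


def test_disjoint_masks_give_zero_coloc():
    pmask = np.zeros((64, 64), dtype=bool)
    pmask[5:20, 5:20] = True
    dmask = np.zeros((64, 64), dtype=bool)
    dmask[40:60, 40:60] = True
    pair = _pair_from_masks(pmask, dmask)
    assert imgmetrics.coloc_ratio(pair) == pytest.approx(0.0, abs=0.02)


def test_synthetic_cage_coloc_recovered():
    ph = synth.NucleusPhenotype("dna_cage", 0.9, 0.9, 0.0)
    vals = [imgmetrics.coloc_ratio(
        synth.generate_nucleus_image(ph, seed=s, noise_sd=0.01))
        for s in range(10)]
    assert np.mean(vals) == pytest.approx(0.9, abs=0.05)


def test_aggregate_phenotype_has_smaller_aggregation_than_diffuse():
    aggs = {}
    for label in ("diffuse", "anti_dna_aggregate"):
        ph = synth.NucleusPhenotype.preset(label)
        aggs[label] = np.mean([
            imgmetrics.aggregation_ratio(
                synth.generate_nucleus_image(ph, seed=s))
            for s in range(6)])
    assert aggs["anti_dna_aggregate"] < aggs["diffuse"]


def test_nuclear_fraction_tracks_cytoplasmic_export():
    ph = synth.NucleusPhenotype("dna_cage", 0.9, 0.5, 0.5)
    vals = [imgmetrics.nuclear_fraction(
        synth.generate_nucleus_image(ph, seed=s, noise_sd=0.01))
        for s in range(8)]
    assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


def test_zero_protein_image_is_missing_value():
    pair = synth.ImagePair(protein=np.full((64, 64), 0.2),
                           dna=np.where(np.eye(64, dtype=bool), 0.9, 0.1))
    assert np.isnan(imgmetrics.coloc_ratio(pair))
    assert np.isnan(imgmetrics.nuclear_fraction(pair))


def test_noiseless_recovery_of_all_three_ratios():
    """On noiseless images the mean of each ratio recovers generator
    truth within +/-0.02."""
    for label in synth.PHENOTYPE_LABELS:
        errs = {"agg": [], "coloc": [], "nf": []}
        for s in range(10):
            pair = synth.generate_nucleus_image(
                synth.NucleusPhenotype.preset(label), seed=s, noise_sd=0.0)
            m = imgmetrics.quantify_pair(pair)
            tr = pair.truth
            agg_truth = tr["protein_mask"].sum() / tr["dna_mask"].sum()
            errs["agg"].append(m.aggregation_ratio - agg_truth)
            errs["coloc"].append(m.coloc_ratio - tr["overlap_fraction"])
            errs["nf"].append(m.nuclear_fraction - tr["overlap_fraction"])
        for key, es in errs.items():
            assert abs(np.mean(es)) <= 0.02, (label, key)


def test_coloc_monotone_in_generator_level():
    levels = np.arange(0.1, 0.95, 0.2)
    means = []
    for level in levels:
        ph = synth.NucleusPhenotype("dna_cage", 0.9, float(level), 0.0)
        means.append(np.mean([
            imgmetrics.coloc_ratio(synth.generate_nucleus_image(ph, seed=s))
            for s in range(6)]))
    assert np.all(np.diff(means) > 0)


def test_channel_asymmetry_is_intentional():
    """Swapping which channel is stored first changes nuclear_fraction
    (methods differ per channel) unless the methods are swapped too."""
    pair = synth.generate_nucleus_image(
        synth.NucleusPhenotype.preset("anti_dna_aggregate"), seed=2)
    swapped = synth.ImagePair(protein=pair.dna, dna=pair.protein)
    a = imgmetrics.nuclear_fraction(pair)
    b = imgmetrics.nuclear_fraction(swapped)
    assert a != pytest.approx(b, abs=1e-6)


# ---------------------------------------------------------------------------
# intensity profiles
# ---------------------------------------------------------------------------

def test_profile_constant_image_is_constant():
    pair = synth.ImagePair(protein=np.full((32, 32), 0.4),
                           dna=np.full((32, 32), 0.7))
    prof = imgmetrics.intensity_profile(pair, (2, 5), (28, 5))
    np.testing.assert_allclose(prof["protein"], 0.4)
    np.testing.assert_allclose(prof["dna"], 0.7)


def test_profile_axis_aligned_matches_row():
    rng = np.random.default_rng(0)
    img = rng.random((16, 40))
    pair = synth.ImagePair(protein=img, dna=img)
    prof = imgmetrics.intensity_profile(pair, (0, 7), (39, 7))
    np.testing.assert_allclose(prof["protein"], img[7, :40])


def test_profile_diagonal_on_ramp_has_directional_slope():
    yy, xx = np.mgrid[0:64, 0:64]
    ramp = (xx + 2.0 * yy) / 256.0
    pair = synth.ImagePair(protein=ramp, dna=ramp)
    prof = imgmetrics.intensity_profile(pair, (0, 0), (40, 40))
    # unit step along the diagonal advances (1,1)/sqrt(2) in pixels
    expected_slope = (1.0 + 2.0) / 256.0 / np.sqrt(2.0)
    slopes = np.diff(prof["protein"]) / np.diff(prof["distance_px"])
    np.testing.assert_allclose(slopes, expected_slope, rtol=1e-9)


def test_profile_errors():
    pair = synth.ImagePair(protein=np.ones((16, 16)), dna=np.ones((16, 16)))
    with pytest.raises(ValueError, match="zero-length"):
        imgmetrics.intensity_profile(pair, (3, 3), (3, 3))
    with pytest.raises(ValueError, match="outside"):
        imgmetrics.intensity_profile(pair, (0, 0), (20, 5))


# ---------------------------------------------------------------------------
# batch quantification
# ---------------------------------------------------------------------------

def test_batch_identical_images_have_zero_sem(two_level_pair):
    per_image, summary = imgmetrics.batch_quantify(
        {"WT": [two_level_pair] * 5})
    assert len(per_image) == 5
    assert summary.loc[0, "coloc_ratio_sem"] == 0.0


def test_batch_group_means_ordered_by_coloc_level():
    groups = {}
    for name, level in (("low", 0.3), ("high", 0.9)):
        ph = synth.NucleusPhenotype("dna_cage", 0.9, level, 0.0)
        groups[name] = [synth.generate_nucleus_image(ph, seed=s)
                        for s in range(6)]
    _, summary = imgmetrics.batch_quantify(groups)
    s = summary.set_index("group")
    assert s.loc["low", "coloc_ratio_mean"] < s.loc["high", "coloc_ratio_mean"]


def test_batch_empty_group_raises():
    with pytest.raises(ValueError, match="nogroup"):
        imgmetrics.batch_quantify({"nogroup": []})


def test_batch_continues_past_failing_image(two_level_pair, monkeypatch):
    calls = {"n": 0}
    real = imgmetrics.quantify_pair

    def flaky(pair):
        calls["n"] += 1
        if calls["n"] == 2:
            raise RuntimeError("corrupt image")
        return real(pair)

    monkeypatch.setattr(imgmetrics, "quantify_pair", flaky)
    with pytest.warns(UserWarning, match="failed"):
        per_image, _ = imgmetrics.batch_quantify(
            {"WT": [two_level_pair] * 3})
    assert (per_image["error"] != "").sum() == 1
    assert len(per_image) == 3
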