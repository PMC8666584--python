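"""FPKM/TE arithmetic, codon frequencies, and the group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tracseq.simulate import TESimConfig, simulate_te_experiment
from tracseq.translation import (
    CDSError,
    NormalizationError,
    classify_te_genes,
    codon_profiles,
    compare_groups,
    correlate_freq_te,
    fpkm,
    m7g_codon_frequency,
    split_by_codon_frequency,
    te_class_codon_profile,
    translation_efficiency,
    translation_ratio,
)


def test_fpkm_arithmetic():
    counts = pd.DataFrame({"lib": [100.0, 1e6 - 100.0]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 1000, "g2": 500})
    out = fpkm(counts, lengths)
    assert out.loc["g1", "lib"] == pytest.approx(100.0)
    assert fpkm(counts.assign(lib=[0.0, 1e6]), lengths).loc["g1", "lib"] == 0.0


def test_fpkm_scale_invariance(rng):
    counts = pd.DataFrame({"lib": rng.integers(1, 500, size=20).astype(float)},
                          index=[f"g{i}" for i in range(20)])
    lengths = pd.Series(rng.integers(300, 3000, size=20), index=counts.index)
    assert np.allclose(fpkm(counts, lengths), fpkm(counts * 10, lengths))


def test_fpkm_zero_total_rejected():
    counts = pd.DataFrame({"lib": [0.0]}, index=["g1"])
    with pytest.raises(NormalizationError):
        fpkm(counts, pd.Series({"g1": 100}))


def test_te_division_and_floor():
    poly = pd.Series({"g1": 30.0, "g2": 5.0})
    inp = pd.Series({"g1": 10.0, "g2": 0.5})
    te = translation_efficiency(poly, inp, min_input_fpkm=1.0)
    assert te["g1"] == pytest.approx(3.0)
    assert np.isnan(te["g2"])  # below the input floor -> masked


def test_te_elementwise_oracle(rng):
    poly = pd.Series(rng.uniform(1, 50, size=30), index=[f"g{i}" for i in range(30)])
    inp = pd.Series(rng.uniform(0.2, 50, size=30), index=poly.index)
    te = translation_efficiency(poly, inp, min_input_fpkm=1.0)
    for g in poly.index:
        expected = poly[g] / inp[g] if inp[g] >= 1.0 else np.nan
        assert te[g] == pytest.approx(expected, nan_ok=True)


def test_translation_ratio_values():
    te_kd = pd.Series({"g1": 2.0, "g2": 1.0})
    te_ctrl = pd.Series({"g1": 2.0, "g2": 2.0})
    tr = translation_ratio(te_kd, te_ctrl)
    assert tr.loc["g1", "translation_ratio"] == 1.0
    assert tr.loc["g1", "log2_translation_ratio"] == 0.0
    assert tr.loc["g2", "translation_ratio"] == 0.5


def test_masked_genes_stay_out_of_downstream_statistics():
    te_kd = pd.Series({"g1": 1.0, "g2": np.nan})
    te_ctrl = pd.Series({"g1": 2.0, "g2": 2.0})
    tr = translation_ratio(te_kd, te_ctrl)
    f = pd.Series({"g1": 0.1, "g2": 0.9, "g3": 0.5})
    with pytest.raises(ValueError):
        # only one finite pair survives alignment -> refuses to correlate
        correlate_freq_te(f, tr["log2_translation_ratio"])


def test_measured_ratio_recovers_truth_slope():
    """At sigma=0, regressing measured log2 TR on truth gives slope ~ 1."""
    sim = simulate_te_experiment(TESimConfig(n_genes=8000, sigma=0.0, seed=9))
    fp = fpkm(sim.counts, sim.lengths)
    tr = translation_ratio(
        translation_efficiency(fp["poly_kd"], fp["input_kd"]),
        translation_efficiency(fp["poly_ctrl"], fp["input_ctrl"]),
    )
    y = tr["log2_translation_ratio"]
    x = sim.truth.set_index("gene_id")["log2_te_ratio_true"].reindex(y.index)
    ok = np.isfinite(x) & np.isfinite(y)
    slope = stats.linregress(x[ok], y[ok]).slope
    assert 0.9 <= slope <= 1.1


def test_codon_frequency_examples():
    prof = m7g_codon_frequency("AAGAAGTTT", {"AAG"})
    assert prof.f == pytest.approx(2 / 3)
    assert m7g_codon_frequency("AAGAAGTTT", frozenset()).f == 0.0


def test_codon_frequency_excludes_terminal_stop():
    assert m7g_codon_frequency("AAGTAA", {"AAG"}).f == 1.0
    # internal stop is counted (with a warning), not dropped
    prof = m7g_codon_frequency("AAGTAATTT", {"AAG"})
    assert prof.f == pytest.approx(1 / 3)


def test_codon_frequency_rejects_bad_frame():
    with pytest.raises(CDSError):
        m7g_codon_frequency("AAGA", {"AAG"})
    with pytest.raises(CDSError):
        m7g_codon_frequency("TAA", {"AAG"})


def test_pearson_on_exact_line():
    f = pd.Series({"g1": 0.1, "g2": 0.2, "g3": 0.4, "g4": 0.5})
    r, p = correlate_freq_te(f, -2.0 * f + 1.0)
    assert r == pytest.approx(-1.0)


def test_pearson_zero_variance_rejected():
    f = pd.Series({"g1": 0.5, "g2": 0.5, "g3": 0.5})
    with pytest.raises(ValueError, match="variance"):
        correlate_freq_te(f, pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0}))


def test_classification_boundaries():
    thr = math.log2(1.5)
    lr = pd.Series({"zero": 0.0, "edge_down": -thr, "edge_up": thr,
                    "down": -1.0, "up": 1.0, "nan": np.nan})
    cls = classify_te_genes(lr, threshold=thr)
    assert cls["zero"] == "other"
    assert cls["edge_down"] == "decreased" and cls["edge_up"] == "increased"
    assert cls["down"] == "decreased" and cls["up"] == "increased"
    assert cls["nan"] == "other"
    # one-line filter oracle on sizes
    assert (cls == "decreased").sum() == int((lr <= -thr).sum())


def test_split_sizes_and_tie_determinism():
    f = pd.Series({f"g{i}": v for i, v in enumerate([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])})
    low, high = split_by_codon_frequency(f, q=0.25)
    assert len(low) == len(high) == 2
    assert set(low) == {"g0", "g1"} and set(high) == {"g6", "g7"}
    tied = pd.Series(0.5, index=[f"g{i}" for i in range(8)])
    low1, high1 = split_by_codon_frequency(tied, q=0.25)
    low2, high2 = split_by_codon_frequency(tied.sample(frac=1, random_state=0), q=0.25)
    assert (low1, high1) == (low2, high2)
    assert len(low1) == len(high1) == 2


def test_split_group_mean_ordering(rng):
    f = pd.Series(rng.uniform(0, 1, size=100), index=[f"g{i}" for i in range(100)])
    low, high = split_by_codon_frequency(f, q=0.25)
    assert f[high].mean() >= f[low].mean()


def test_split_rejects_too_few_genes():
    with pytest.raises(ValueError):
        split_by_codon_frequency(pd.Series({"g1": 0.5}), q=0.25)


def test_mannwhitney_identical_groups():
    g = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert g.p_value == pytest.approx(1.0)
    assert g.direction == "a~b"


def test_mannwhitney_fully_separated_3v3():
    g = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert g.p_value == pytest.approx(0.1)  # 2 / C(6,3)


def test_mannwhitney_matches_scipy_exact(rng):
    for _ in range(5):
        a = rng.normal(0, 1, size=5)
        b = rng.normal(0.8, 1, size=5)
        g = compare_groups(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert g.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_mannwhitney_small_group_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


def test_te_class_profile_single_gene():
    classes = pd.Series({"g1": "decreased"})
    table = te_class_codon_profile(classes, {"g1": "AAGAAGAAG"}, {"AAG"})
    assert table.loc[0, "codon"] == "AAG"
    assert table.loc[0, "mean_frequency"] == pytest.approx(1.0)
    assert bool(table.loc[0, "is_m7g_codon"])


def test_te_class_profile_uniform_codons(rng):
    """Uniform random sense codons -> every codon frequency ~ 1/61."""
    sense = [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
             if c not in {"TAA", "TAG", "TGA"}]
    cds = {"g1": "".join(rng.choice(sense, size=5000))}
    table = te_class_codon_profile(pd.Series({"g1": "decreased"}), cds, {"AAG"})
    assert np.allclose(table["mean_frequency"], 1 / 61, atol=0.012)


def test_te_class_profile_recovers_implanted_effect():
    """With beta > 0, TE-decreased genes are m7G-codon-rich."""
    cfg = TESimConfig(n_genes=2000, beta=2.0, sigma=0.2, seed=21)
    sim = simulate_te_experiment(cfg)
    fp = fpkm(sim.counts, sim.lengths)
    tr = translation_ratio(
        translation_efficiency(fp["poly_kd"], fp["input_kd"]),
        translation_efficiency(fp["poly_ctrl"], fp["input_ctrl"]),
    )
    classes = classify_te_genes(tr["log2_translation_ratio"])
    f = codon_profiles(sim.cds, cfg.m7g_codons)
    means = f.groupby(classes).mean()
    assert means["decreased"] > means["increased"]
    assert means["decreased"] > means["other"]
    with pytest.raises(ValueError):
        te_class_codon_profile(pd.Series({"g1": "other"}), sim.cds, cfg.m7g_codons)
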