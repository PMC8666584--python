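"""Pileups, cleavage statistics, site calling and the paired level test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import brute_force_pileup
from tracseq import trac
from tracseq.simulate import TracSimConfig, simulate_trac_library
from tracseq.trac import (
    CleavageProfile,
    CleavageScoreTrack,
    M7GCall,
    PairingError,
    SitePileup,
    call_m7g_sites,
    cleavage_ratio,
    cleavage_score,
    compare_methylation_paired,
    compute_pileup,
    methylation_levels,
    site_motif,
)


def _aln(rows):
    return pd.DataFrame(rows, columns=["trna_id", "start", "end"])


def test_single_read_pileup():
    pl = compute_pileup(_aln([("t1", 1, 20)]), {"t1": 79})[0]
    assert (pl.depth[:20] == 1).all() and (pl.depth[20:] == 0).all()
    assert pl.starts[0] == 1 and pl.starts[1:].sum() == 0


def test_two_read_pileup_at_shared_site():
    pl = compute_pileup(_aln([("t1", 1, 79), ("t1", 46, 79)]), {"t1": 79})[0]
    assert pl.depth[45] == 2
    assert pl.starts[45] == 1


def test_pileup_matches_brute_force_oracle(rng):
    length = 80
    starts = rng.integers(1, length + 1, size=100)
    ends = np.minimum(starts + rng.integers(0, 40, size=100), length)
    table = _aln([("t1", int(s), int(e)) for s, e in zip(starts, ends)])
    pl = compute_pileup(table, {"t1": length})[0]
    depth, start_counts = brute_force_pileup(table, length)
    assert np.array_equal(pl.depth, depth)
    assert np.array_equal(pl.starts, start_counts)
    # conservation: every counted read starts exactly once
    assert pl.starts.sum() == len(table)
    assert (pl.starts <= pl.depth).all()


def test_pileup_rejects_bad_records():
    with pytest.raises(ValueError, match="unknown"):
        compute_pileup(_aln([("ghost", 1, 5)]), {"t1": 79})
    with pytest.raises(ValueError, match="end < start"):
        compute_pileup(_aln([("t1", 10, 5)]), {"t1": 79})


def test_pileup_from_sam_matches_table(tmp_path):
    """SAM input (via pysam) gives the same pileup as the alignment table."""
    length = 50
    seq = "A" * length
    sam = tmp_path / "reads.sam"
    lines = ["@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:t1\tLN:{length}"]
    rows = []
    for i, (s, e) in enumerate([(1, 20), (5, 30), (5, 50), (46, 50)]):
        lines.append(f"r{i}\t0\tt1\t{s}\t60\t{e - s + 1}M\t*\t0\t0\t{seq[s - 1:e]}\t*")
        rows.append(("t1", s, e))
    # secondary (0x100) and unmapped (0x4) records must be ignored
    lines.append(f"r9\t256\tt1\t2\t60\t5M\t*\t0\t0\t{seq[:5]}\t*")
    lines.append("r10\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*")
    sam.write_text("\n".join(lines) + "\n")
    from_sam = compute_pileup(sam, {"t1": length})[0]
    from_table = compute_pileup(_aln(rows), {"t1": length})[0]
    assert np.array_equal(from_sam.depth, from_table.depth)
    assert np.array_equal(from_sam.starts, from_table.starts)


def test_cleavage_ratio_arithmetic_and_masking():
    pl = SitePileup("t1", depth=[50, 0, 10], starts=[5, 0, 3])
    prof = cleavage_ratio(pl, min_depth=20)
    assert prof.ratio[0] == pytest.approx(0.1)
    assert np.isnan(prof.ratio[1])  # zero depth is masked, not 0
    assert np.isnan(prof.ratio[2])  # below the floor is masked too
    full = cleavage_ratio(pl, min_depth=1)
    expected = np.array([5 / 50, np.nan, 3 / 10])
    assert np.allclose(full.ratio, expected, equal_nan=True)


def test_cleavage_score_values_and_antisymmetry():
    t = CleavageProfile("t1", np.array([0.25, 0.32, np.nan]))
    c = CleavageProfile("t1", np.array([0.25, 0.02, 0.5]))
    track = cleavage_score(t, c)
    assert track.score[0] == pytest.approx(0.0)
    assert track.score[1] == pytest.approx(4.0)  # log2(16)
    assert np.isnan(track.score[2])
    flipped = cleavage_score(c, t)
    assert np.allclose(track.score, -flipped.score, equal_nan=True)


def test_cleavage_score_epsilon_floor():
    t = CleavageProfile("t1", np.array([0.3]))
    c = CleavageProfile("t1", np.array([0.0]))
    track = cleavage_score(t, c, epsilon=1e-4)
    assert track.score[0] == pytest.approx(np.log2(0.3 / 1e-4))


def test_literal_formula_reading_stays_small():
    """The ratio-of-logs reading of the score cannot clear the >4 threshold."""
    t = CleavageProfile("t1", np.array([0.3]))
    c = CleavageProfile("t1", np.array([0.01]))
    literal = cleavage_score(t, c, literal_formula=True).score[0]
    quotient = cleavage_score(t, c).score[0]
    assert literal == pytest.approx(np.log2(0.3) / np.log2(0.01))
    assert literal < 1 < 4 < quotient


def test_score_requires_matching_trna():
    with pytest.raises(PairingError):
        cleavage_score(CleavageProfile("a", np.zeros(3)), CleavageProfile("b", np.zeros(3)))


def _track_with(pos_scores, length=79, trna_id="t1"):
    score = np.full(length, 0.0)
    for pos, s in pos_scores.items():
        score[pos - 1] = s
    return CleavageScoreTrack(trna_id, score, epsilon=1e-4)


def _profile_with(pos_ratios, length=79, trna_id="t1"):
    ratio = np.full(length, 0.0)
    for pos, r in pos_ratios.items():
        ratio[pos - 1] = r
    return CleavageProfile(trna_id, ratio)


def test_call_inside_window():
    calls = call_m7g_sites(_track_with({47: 4.5}), _profile_with({47: 0.15}))
    assert calls == [M7GCall("t1", 47, 4.5, 0.15, True)]


def test_no_call_outside_window():
    assert call_m7g_sites(_track_with({30: 10.0}), _profile_with({30: 0.5})) == []


@pytest.mark.parametrize("score,ratio", [(4.0, 0.15), (4.5, 0.1), (4.0, 0.1)])
def test_thresholds_are_strict(score, ratio):
    assert call_m7g_sites(_track_with({46: score}), _profile_with({46: ratio})) == []


def test_methylation_level_is_window_max():
    track = _track_with({46: 1.0, 47: 5.0, 48: 2.0})
    (lv,) = methylation_levels([track], condition="ctrl")
    assert lv.level == 5.0
    same = methylation_levels([track, track])
    assert same[0].level == same[1].level


def test_knockdown_lowers_median_level(small_panel):
    reference, truth = small_panel
    def levels(p_treat, seed):
        cfg = TracSimConfig(n_trnas=20, modified_fraction=0.5, seed=seed, p_cleave_treated=p_treat)
        tracks = {}
        profs = {}
        for arm in ("treated", "non_treated"):
            _, aln = simulate_trac_library(reference, truth, cfg, arm, emit_reads=False)
            profs[arm] = {p.trna_id: cleavage_ratio(p) for p in compute_pileup(aln, reference)}
        mod = truth.loc[truth["modified"], "trna_id"]
        return {
            t: methylation_levels([cleavage_score(profs["treated"][t], profs["non_treated"][t])])[0].level
            for t in mod
        }
    ctrl = levels(0.3, seed=11)
    kd = levels(0.15, seed=12)
    assert np.median(list(kd.values())) < np.median(list(ctrl.values()))


def test_wilcoxon_all_positive_one_sided():
    diffs_pos = [1.0, 2.0, 0.5, 3.0, 1.5, 2.5]
    _, p = compare_methylation_paired(diffs_pos, [0.0] * 6, alternative="greater")
    assert p == pytest.approx(1 / 64)


def test_wilcoxon_symmetric_two_sided():
    a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    b = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]  # differences +-1 alternating
    _, p = compare_methylation_paired(a, b)
    assert p == pytest.approx(1.0)


def test_wilcoxon_matches_scipy_exact_enumeration(rng):
    for _ in range(5):
        diffs = rng.normal(0.3, 1.0, size=10).round(3)
        diffs = diffs[diffs != 0]
        w, p = compare_methylation_paired(diffs, np.zeros_like(diffs))
        ref = stats.wilcoxon(diffs, method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_degenerate_and_pairing_errors():
    with pytest.raises(ValueError, match="zero"):
        compare_methylation_paired([1.0] * 6, [1.0] * 6)
    from tracseq.trac import MethylationLevel
    a = [MethylationLevel("t1", 1.0), MethylationLevel("t2", 2.0)]
    b = [MethylationLevel("t1", 1.5), MethylationLevel("t3", 2.5)]
    with pytest.raises(PairingError):
        compare_methylation_paired(a, b)


def test_motif_single_call_is_one_hot(small_panel):
    reference, truth = small_panel
    row = truth[truth["modified"]].iloc[0]
    m = next(r for r in reference if r.trna_id == row["trna_id"])
    pos = int(row["m7g_position"])
    call = M7GCall(m.trna_id, pos, 5.0, 0.3, True)
    motif = site_motif([call], reference, flank=3)
    for off in range(-3, 4):
        col = motif[off]
        assert col.sum() == pytest.approx(1.0)
        assert col[m.sequence[pos - 1 + off]] == 1.0


def test_motif_center_is_all_g_and_matches_tally(small_panel):
    reference, truth = small_panel
    calls = [
        M7GCall(r["trna_id"], int(r["m7g_position"]), 5.0, 0.3, True)
        for _, r in truth[truth["modified"]].iterrows()
    ]
    flank = 2
    motif = site_motif(calls, reference, flank=flank)
    assert motif.loc["G", 0] == 1.0
    # hand tally oracle
    seqs = {m.trna_id: m.sequence for m in reference}
    for off in range(-flank, flank + 1):
        tally = {"A": 0, "C": 0, "G": 0, "T": 0}
        for c in calls:
            tally[seqs[c.trna_id][c.position - 1 + off]] += 1
        total = sum(tally.values())
        for base in "ACGT":
            assert motif.loc[base, off] == pytest.approx(tally[base] / total)


def test_motif_requires_calls(small_panel):
    reference, _ = small_panel
    with pytest.raises(ValueError, match="empty"):
        site_motif([], reference)


def test_caller_round_trip_single_seed(small_panel, small_trac_config):
    """All implanted sites called, no unmodified tRNA called (one seed here;
    the multi-seed sweep lives in the acceptance suite)."""
    reference, truth = small_panel
    profs = {}
    for arm in ("treated", "non_treated"):
        _, aln = simulate_trac_library(reference, truth, small_trac_config, arm, emit_reads=False)
        profs[arm] = {p.trna_id: cleavage_ratio(p) for p in compute_pileup(aln, reference)}
    called = {}
    for tid in profs["treated"]:
        track = cleavage_score(profs["treated"][tid], profs["non_treated"][tid])
        for c in call_m7g_sites(track, profs["treated"][tid]):
            called.setdefault(tid, set()).add(c.position)
    expected = {
        r["trna_id"]: {int(r["m7g_position"])} for _, r in truth[truth["modified"]].iterrows()
    }
    assert called == expected
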