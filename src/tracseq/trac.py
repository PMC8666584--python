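"""TRAC-seq site statistics: pileups, cleavage ratios and scores, m7G calls.

The chemistry (NaBH4 reduction of m7G followed by aniline scission) cleaves
the tRNA backbone at modified guanosines, so the 5' end of the downstream
fragment maps exactly at the modified position.  In a cleavage-treated
library this shows up as an excess of read *starts* at the site relative to
the untreated control.  Per site i on a mature tRNA:

    cleavage ratio   r_i = s_i / d_i        (read starts / read depth)
    cleavage score   score_i = log2( max(r_i^treated, eps) / max(r_i^control, eps) )

A position in the variable-loop window 46-48 is called m7G-modified when
score > 4 and the treated-arm ratio > 0.1, both strict.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import MatureTRNA

__all__ = [
    "SitePileup",
    "CleavageProfile",
    "CleavageScoreTrack",
    "M7GCall",
    "MethylationLevel",
    "compute_pileup",
    "cleavage_ratio",
    "cleavage_score",
    "call_m7g_sites",
    "methylation_levels",
    "compare_methylation_paired",
    "site_motif",
    "write_site_track",
    "write_calls",
]

M7G_WINDOW = (46, 48)          # 1-based mature-sequence positions, inclusive
MIN_DEPTH_DEFAULT = 20         # per-site per-arm depth floor; shallower sites masked
EPSILON_DEFAULT = 1e-4         # pseudo-ratio; below anything observable at the depth floor
SCORE_THRESHOLD = 4.0          # strict: score must exceed this
RATIO_THRESHOLD = 0.1          # strict: treated-arm ratio must exceed this


class PairingError(ValueError):
    """Raised when treated/control tracks do not refer to the same tRNA set."""


@dataclass
class SitePileup:
    """Per-position read depth and read-start counts over one mature tRNA."""

    trna_id: str
    depth: np.ndarray
    starts: np.ndarray
    library_id: str = ""
    arm: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.depth.shape != self.starts.shape:
            raise ValueError(f"{self.trna_id}: depth/starts length mismatch")
        if (self.starts > self.depth).any() or (self.depth < 0).any():
            raise ValueError(f"{self.trna_id}: invalid pileup (starts > depth or negative)")


@dataclass
class CleavageProfile:
    """Per-position cleavage ratio s_i/d_i; NaN marks masked (shallow) sites."""

    trna_id: str
    ratio: np.ndarray
    arm: str = ""


@dataclass
class CleavageScoreTrack:
    trna_id: str
    score: np.ndarray
    epsilon: float


@dataclass(frozen=True)
class M7GCall:
    trna_id: str
    position: int
    cleavage_score: float
    treated_ratio: float
    passed: bool


@dataclass(frozen=True)
class MethylationLevel:
    """Per-tRNA methylation level: the best cleavage score in the 46-48 window.

    The level is this package's summary of per-tRNA m7G signal; it is what
    the paired condition comparison operates on.
    """

    trna_id: str
    level: float
    condition: str = ""


def _reference_lengths(reference) -> dict[str, int]:
    if isinstance(reference, Mapping):
        return {k: int(v) for k, v in reference.items()}
    return {m.trna_id: m.length for m in reference}


def _pileup_from_table(table: pd.DataFrame, lengths: dict[str, int], library_id: str, arm: str) -> list[SitePileup]:
    required = {"trna_id", "start", "end"}
    if not required.issubset(table.columns):
        raise ValueError(f"alignment table needs columns {sorted(required)}")
    out = []
    for tid, grp in table.groupby("trna_id", sort=True):
        if tid not in lengths:
            raise ValueError(f"alignment to unknown tRNA {tid!r}")
        n = lengths[tid]
        start = grp["start"].to_numpy(dtype=np.int64)
        end = grp["end"].to_numpy(dtype=np.int64)
        if (end < start).any():
            raise ValueError(f"malformed alignment record on {tid}: end < start")
        if (start < 1).any() or (end > n).any():
            raise ValueError(f"alignment out of bounds on {tid} (length {n})")
        # depth via interval difference array; starts via bincount
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, start - 1, 1)
        np.add.at(diff, end, -1)
        depth = np.cumsum(diff[:n])
        starts = np.bincount(start - 1, minlength=n)
        out.append(SitePileup(trna_id=tid, depth=depth, starts=starts, library_id=library_id, arm=arm))
    return out


def _pileup_from_sam(path: str | Path, lengths: dict[str, int], library_id: str, arm: str) -> list[SitePileup]:
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            # primary alignments only; soft clips do not shift the reported start
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append((rec.reference_name, rec.reference_start + 1, rec.reference_end))
    table = pd.DataFrame(rows, columns=["trna_id", "start", "end"])
    return _pileup_from_table(table, lengths, library_id, arm)


def compute_pileup(
    alignments: pd.DataFrame | str | Path,
    reference: Iterable[MatureTRNA] | Mapping[str, int],
    library_id: str = "",
    arm: str = "",
) -> list[SitePileup]:
    """Per-tRNA depth and read-start vectors from an alignment table or SAM/BAM.

    Coordinates are 1-based inclusive on the mature sequence.  Depth d_i
    counts reads overlapping position i; s_i counts reads whose alignment
    begins exactly at i.  Unmapped, secondary and supplementary records are
    excluded.  tRNAs with zero reads are omitted (treat as all-zero).
    """
    lengths = _reference_lengths(reference)
    if isinstance(alignments, (str, Path)):
        p = str(alignments)
        if p.endswith((".sam", ".bam")):
            return _pileup_from_sam(p, lengths, library_id, arm)
        alignments = pd.read_csv(p, sep="\t", comment="#")
    return _pileup_from_table(alignments, lengths, library_id, arm)


def cleavage_ratio(pileup: SitePileup, min_depth: int = MIN_DEPTH_DEFAULT) -> CleavageProfile:
    """r_i = s_i / d_i where d_i >= min_depth; shallower positions are NaN-masked."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    ratio = np.full(pileup.depth.shape, np.nan)
    ok = pileup.depth >= min_depth
    ratio[ok] = pileup.starts[ok] / pileup.depth[ok]
    return CleavageProfile(trna_id=pileup.trna_id, ratio=ratio, arm=pileup.arm)


def cleavage_score(
    treated: CleavageProfile,
    non_treated: CleavageProfile,
    epsilon: float = EPSILON_DEFAULT,
    literal_formula: bool = False,
) -> CleavageScoreTrack:
    """Per-site log2 enrichment of treated over non-treated cleavage ratio.

    Default: score_i = log2(max(r_t, eps) / max(r_c, eps)).  The
    ``literal_formula`` flag computes log2(r_t)/log2(r_c) instead (a
    typographically possible alternative reading); it is not used for
    calling because its range cannot reach the >4 threshold for
    realistically enriched sites.
    """
    if treated.trna_id != non_treated.trna_id:
        raise PairingError(f"arm mismatch: {treated.trna_id!r} vs {non_treated.trna_id!r}")
    if treated.ratio.shape != non_treated.ratio.shape:
        raise PairingError(f"{treated.trna_id}: arms have different lengths")
    rt = np.maximum(treated.ratio, epsilon)
    rc = np.maximum(non_treated.ratio, epsilon)
    if literal_formula:
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.log2(rt) / np.log2(rc)
    else:
        score = np.log2(rt / rc)
    score[np.isnan(treated.ratio) | np.isnan(non_treated.ratio)] = np.nan
    return CleavageScoreTrack(trna_id=treated.trna_id, score=score, epsilon=epsilon)


def call_m7g_sites(
    scores: CleavageScoreTrack,
    treated: CleavageProfile,
    window: tuple[int, int] = M7G_WINDOW,
    min_score: float = SCORE_THRESHOLD,
    min_ratio: float = RATIO_THRESHOLD,
) -> list[M7GCall]:
    """Call m7G sites: positions in the window with score > min_score and
    treated ratio > min_ratio (both strict).  Returns passing calls only."""
    if scores.trna_id != treated.trna_id:
        raise PairingError(f"score/profile mismatch: {scores.trna_id!r} vs {treated.trna_id!r}")
    calls = []
    lo, hi = window
    for pos in range(lo, min(hi, len(scores.score)) + 1):
        sc = scores.score[pos - 1]
        rt = treated.ratio[pos - 1]
        if np.isnan(sc) or np.isnan(rt):
            continue
        if sc > min_score and rt > min_ratio:
            calls.append(
                M7GCall(trna_id=scores.trna_id, position=pos, cleavage_score=float(sc), treated_ratio=float(rt), passed=True)
            )
    return calls


def methylation_levels(
    score_tracks: Mapping[str, CleavageScoreTrack] | Sequence[CleavageScoreTrack],
    condition: str = "",
    window: tuple[int, int] = M7G_WINDOW,
) -> list[MethylationLevel]:
    """Per-tRNA level = max cleavage score over the 46-48 window (NaN-aware)."""
    tracks = score_tracks.values() if isinstance(score_tracks, Mapping) else score_tracks
    lo, hi = window
    out = []
    for tr in tracks:
        seg = tr.score[lo - 1 : hi]
        level = float(np.nanmax(seg)) if seg.size and not np.all(np.isnan(seg)) else float("nan")
        out.append(MethylationLevel(trna_id=tr.trna_id, level=level, condition=condition))
    return out


# ---------------------------------------------------------------------------
# Paired comparison of methylation levels (Wilcoxon signed-rank)
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(diffs: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank by full enumeration of 2^n sign assignments.

    Ties among |d| receive midranks; the enumeration remains exact under the
    sign-flip null.  Returns (W+, p)."""
    absd = np.abs(diffs)
    ranks = stats.rankdata(absd)
    w_obs = float(ranks[diffs > 0].sum())
    n = len(diffs)
    # distribution of W+ over all sign vectors
    stats_all = np.zeros(1)
    for r in ranks:
        stats_all = np.concatenate([stats_all, stats_all + r])
    total = stats_all.size
    tol = 1e-9
    p_ge = np.count_nonzero(stats_all >= w_obs - tol) / total
    p_le = np.count_nonzero(stats_all <= w_obs + tol) / total
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_obs, p


def compare_methylation_paired(
    control: Sequence[MethylationLevel] | Sequence[float],
    knockdown: Sequence[MethylationLevel] | Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 15,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired per-tRNA methylation levels.

    Pairs with zero difference are dropped (signed-rank convention); the
    null distribution is enumerated exactly for n <= ``exact_max_n``
    (32768 sign vectors at most) and normally approximated beyond that.
    Returns (W+, p-value).
    """

    def _values(xs):
        if xs and isinstance(xs[0], MethylationLevel):
            return {x.trna_id: x.level for x in xs}
        return np.asarray(xs, dtype=float)

    a, b = _values(list(control)), _values(list(knockdown))
    if isinstance(a, dict) or isinstance(b, dict):
        if not (isinstance(a, dict) and isinstance(b, dict)):
            raise PairingError("mixed level/array inputs")
        if set(a) != set(b):
            raise PairingError("control and knockdown cover different tRNA sets")
        keys = sorted(a)
        a = np.array([a[k] for k in keys])
        b = np.array([b[k] for k in keys])
    if len(a) != len(b):
        raise PairingError("paired vectors differ in length")
    diffs = a - b
    diffs = diffs[~np.isnan(diffs)]
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("degenerate test: all paired differences are zero")
    if diffs.size < 5:
        raise ValueError(f"need >= 5 nonzero paired differences, got {diffs.size}")
    if diffs.size <= exact_max_n:
        return _signed_rank_exact_p(diffs, alternative)
    res = stats.wilcoxon(diffs, alternative=alternative, method="approx", correction=True)
    # report W+ (sum of positive ranks) for consistency with the exact branch
    ranks = stats.rankdata(np.abs(diffs))
    return float(ranks[diffs > 0].sum()), float(res.pvalue)


# ---------------------------------------------------------------------------
# Site-flanking sequence motif
# ---------------------------------------------------------------------------

def site_motif(
    calls: Sequence[M7GCall],
    reference: Sequence[MatureTRNA],
    flank: int = 5,
) -> pd.DataFrame:
    """Base-frequency matrix (rows A/C/G/T) over +-flank around called sites.

    Columns are offsets -flank..+flank; each column sums to 1 over the calls
    that actually cover it (edge positions reduce the usable count).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if not calls:
        raise ValueError("cannot build a motif from an empty call set")
    seqs = {m.trna_id: m.sequence for m in reference}
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=np.int64)
    base_row = {"A": 0, "C": 1, "G": 2, "T": 3}
    for call in calls:
        seq = seqs[call.trna_id]
        for off in range(-flank, flank + 1):
            pos = call.position + off  # 1-based
            if 1 <= pos <= len(seq):
                counts[base_row[seq[pos - 1]], off + flank] += 1
    col_totals = counts.sum(axis=0)
    freq = np.divide(counts, col_totals, where=col_totals > 0, out=np.zeros_like(counts, dtype=float))
    return pd.DataFrame(freq, index=list("ACGT"), columns=range(-flank, flank + 1))


# ---------------------------------------------------------------------------
# TSV writers (header lines begin '#'; coordinates 1-based inclusive)
# ---------------------------------------------------------------------------

def write_site_track(
    path: str | Path,
    pileups_t: Mapping[str, SitePileup],
    pileups_c: Mapping[str, SitePileup],
    profiles_t: Mapping[str, CleavageProfile],
    profiles_c: Mapping[str, CleavageProfile],
    scores: Mapping[str, CleavageScoreTrack],
    header_extra: str = "",
) -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("# trna_id\tposition\tdepth_t\tstarts_t\tdepth_c\tstarts_c\tratio_t\tratio_c\tscore\tmasked\n")
        for tid in sorted(scores):
            sc = scores[tid].score
            for i in range(len(sc)):
                rt = profiles_t[tid].ratio[i]
                rc = profiles_c[tid].ratio[i]
                masked = int(np.isnan(sc[i]))
                fh.write(
                    f"{tid}\t{i + 1}\t{pileups_t[tid].depth[i]}\t{pileups_t[tid].starts[i]}\t"
                    f"{pileups_c[tid].depth[i]}\t{pileups_c[tid].starts[i]}\t"
                    f"{'NA' if np.isnan(rt) else f'{rt:.6g}'}\t{'NA' if np.isnan(rc) else f'{rc:.6g}'}\t"
                    f"{'NA' if masked else f'{sc[i]:.6g}'}\t{masked}\n"
                )


def write_calls(path: str | Path, calls: Sequence[M7GCall], header_extra: str = "") -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("# trna_id\tposition\tcleavage_score\ttreated_ratio\tpassed\n")
        for c in calls:
            fh.write(f"{c.trna_id}\t{c.position}\t{c.cleavage_score:.6g}\t{c.treated_ratio:.6g}\t{int(c.passed)}\n")
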