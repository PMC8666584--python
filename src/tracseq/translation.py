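"""Polysome-based translation-efficiency analysis and m7G codon statistics.

Per gene: FPKM from fragment counts, TE = FPKM_polysome / FPKM_input,
translation ratio = TE_knockdown / TE_control, and the m7G-codon frequency
f of its CDS (fraction of codons decoded by m7G-modified tRNAs, terminal
stop codon excluded).  Statistics: Pearson correlation of f with log2
translation ratio, quantile-group Mann-Whitney comparisons, and the
per-codon frequency profile of TE-decreased genes.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import M7GCodonSet, STOP_CODONS

__all__ = [
    "TE_THRESHOLD_DEFAULT",
    "MIN_INPUT_FPKM_DEFAULT",
    "CodonProfile",
    "GroupComparison",
    "fpkm",
    "translation_efficiency",
    "translation_ratio",
    "m7g_codon_frequency",
    "codon_profiles",
    "correlate_freq_te",
    "classify_te_genes",
    "split_by_codon_frequency",
    "compare_groups",
    "te_class_codon_profile",
]

logger = logging.getLogger(__name__)

TE_THRESHOLD_DEFAULT = math.log2(1.5)   # |log2 TR| cutoff for TE classes
MIN_INPUT_FPKM_DEFAULT = 1.0            # input-FPKM floor; shallower genes masked
QUANTILE_DEFAULT = 0.25                 # tail size for the low/high f split


class NormalizationError(ValueError):
    pass


class CDSError(ValueError):
    pass


@dataclass(frozen=True)
class CodonProfile:
    """Codon counts of one CDS and its m7G-codon frequency f."""

    gene_id: str
    codon_counts: Mapping[str, int]
    f: float


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    direction: str  # 'a>b', 'a<b' or 'a~b' by median


def fpkm(counts: pd.DataFrame | pd.Series, lengths: pd.Series) -> pd.DataFrame | pd.Series:
    """FPKM = count / (length_kb * total_fragments / 1e6), per library (column)."""
    if isinstance(counts, pd.Series):
        return fpkm(counts.to_frame("lib"), lengths)["lib"]
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise NormalizationError("missing or non-positive gene length")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise NormalizationError(f"zero total fragments in libraries {bad}")
    return counts.div(totals / 1e6, axis=1).div(lengths / 1000.0, axis=0)


def translation_efficiency(
    polysome_fpkm: pd.Series,
    input_fpkm: pd.Series,
    min_input_fpkm: float = MIN_INPUT_FPKM_DEFAULT,
) -> pd.Series:
    """TE = polysome FPKM / input FPKM; genes below the input floor are NaN."""
    polysome_fpkm, input_fpkm = polysome_fpkm.align(input_fpkm, join="inner")
    te = polysome_fpkm / input_fpkm
    te[input_fpkm < min_input_fpkm] = np.nan
    te.name = "te"
    return te


def translation_ratio(te_kd: pd.Series, te_ctrl: pd.Series) -> pd.DataFrame:
    """TE(knockdown)/TE(control) with its log2; defined only where both TEs are."""
    te_kd, te_ctrl = te_kd.align(te_ctrl, join="inner")
    ratio = te_kd / te_ctrl
    out = pd.DataFrame({"translation_ratio": ratio, "log2_translation_ratio": np.log2(ratio)})
    out.index.name = "gene_id"
    return out


def m7g_codon_frequency(cds: str, codon_set: M7GCodonSet | Sequence[str], gene_id: str = "") -> CodonProfile:
    """Codon profile of a CDS in frame 0; f = set codons / counted codons.

    The terminal stop codon, if present, is excluded from both numerator
    and denominator; an internal stop is counted but logged as a warning.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise CDSError(f"CDS length {len(cds)} of {gene_id!r} is not a positive multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
        if not codons:
            raise CDSError(f"CDS of {gene_id!r} consists of a stop codon only")
    internal_stops = sum(c in STOP_CODONS for c in codons)
    if internal_stops:
        logger.warning("CDS %r contains %d internal stop codon(s)", gene_id, internal_stops)
    counts = Counter(codons)
    members = codon_set.codons if isinstance(codon_set, M7GCodonSet) else frozenset(codon_set)
    in_set = sum(n for c, n in counts.items() if c in members)
    return CodonProfile(gene_id=gene_id, codon_counts=dict(counts), f=in_set / len(codons))


def codon_profiles(cds_by_gene: Mapping[str, str], codon_set: M7GCodonSet | Sequence[str]) -> pd.Series:
    """Vector of m7G-codon frequencies f over a CDS collection."""
    out = pd.Series(
        {gid: m7g_codon_frequency(seq, codon_set, gene_id=gid).f for gid, seq in cds_by_gene.items()},
        name="f",
    )
    out.index.name = "gene_id"
    return out


def correlate_freq_te(f: pd.Series, te_values: pd.Series) -> tuple[float, float]:
    """Pearson r (and two-sided p via the t transform) between f and a TE
    statistic, paired by gene id; non-finite pairs dropped."""
    f, te_values = f.align(te_values, join="inner")
    ok = np.isfinite(f) & np.isfinite(te_values)
    x, y = f[ok].to_numpy(), te_values[ok].to_numpy()
    if len(x) < 3:
        raise ValueError(f"need >= 3 finite pairs, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classify_te_genes(log2_ratios: pd.Series, threshold: float = TE_THRESHOLD_DEFAULT) -> pd.Series:
    """'decreased' if log2 TR <= -threshold, 'increased' if >= +threshold,
    else 'other'; boundaries inclusive toward the extreme classes."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    cls = pd.Series("other", index=log2_ratios.index, name="te_class")
    cls[log2_ratios <= -threshold] = "decreased"
    cls[log2_ratios >= threshold] = "increased"
    cls[~np.isfinite(log2_ratios)] = "other"
    return cls


def split_by_codon_frequency(f: pd.Series, q: float = QUANTILE_DEFAULT) -> tuple[list, list]:
    """Bottom-q and top-q gene groups by f; equal sizes by construction,
    ties broken by gene-id sort order."""
    if not 0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    k = int(q * len(f))
    if k < 1:
        raise ValueError(f"fewer than {math.ceil(1 / q)} genes for q={q}")
    ordered = f.sort_index().sort_values(kind="stable")
    return list(ordered.index[:k]), list(ordered.index[-k:])


def _mannwhitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact Mann-Whitney by enumeration of all C(n_a+n_b, n_a) group
    assignments of the pooled observations (ties handled by 1/2 counts)."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_stat(x, y):
        return float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))

    u_obs = u_stat(a, b)
    us = []
    idx = np.arange(n)
    for comb in itertools.combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        us.append(u_stat(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    tol = 1e-9
    p_ge = np.count_nonzero(us >= u_obs - tol) / len(us)
    p_le = np.count_nonzero(us <= u_obs + tol) / len(us)
    return u_obs, min(1.0, 2.0 * min(p_ge, p_le))


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    exact_max_n: int = 12,
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two gene groups.

    Exact null by enumeration when n_a + n_b <= ``exact_max_n``; otherwise
    the tie-corrected normal approximation (with continuity correction).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 finite values")
    if len(a) + len(b) <= exact_max_n:
        u, p = _mannwhitney_exact(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    med_a, med_b = np.median(a), np.median(b)
    direction = "a>b" if med_a > med_b else ("a<b" if med_a < med_b else "a~b")
    return GroupComparison(
        group_a=label_a, group_b=label_b, n_a=len(a), n_b=len(b),
        statistic=u, p_value=p, direction=direction,
    )


def te_class_codon_profile(
    te_classes: pd.Series,
    cds_by_gene: Mapping[str, str],
    codon_set: M7GCodonSet | Sequence[str],
    te_class: str = "decreased",
) -> pd.DataFrame:
    """Mean per-codon frequency across genes of one TE class, ranked.

    Per gene, each codon's frequency is its count over the gene's counted
    codons (terminal stop excluded); the table flags m7G-set membership.
    """
    genes = [g for g in te_classes.index if te_classes[g] == te_class and g in cds_by_gene]
    if not genes:
        raise ValueError(f"no genes in TE class {te_class!r}")
    members = codon_set.codons if isinstance(codon_set, M7GCodonSet) else frozenset(codon_set)
    acc: Counter = Counter()
    for g in genes:
        prof = m7g_codon_frequency(cds_by_gene[g], members, gene_id=g)
        total = sum(prof.codon_counts.values())
        for c, n in prof.codon_counts.items():
            acc[c] += n / total
    table = pd.DataFrame(
        {
            "codon": list(acc),
            "mean_frequency": [acc[c] / len(genes) for c in acc],
            "is_m7g_codon": [c in members for c in acc],
        }
    )
    return table.sort_values(
        ["mean_frequency", "codon"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
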