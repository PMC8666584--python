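"""tRNA expression quantification and bench-quantification formulas.

Read counting follows the exclusive-mapping policy for ALKB-treated tRNA
libraries: per read, only best-score hits are kept; when best hits include
both a genomic locus and a mature tRNA, the genomic hits are dropped; a
read tied across k mature tRNAs contributes 1/k to each.  Expression is
RPKM-normalized and a tRNA is "expressed" when RPKM > 10,000 (strict).

Also provided: relative qPCR quantification (2^-ddCt, serving both
standard qRT-PCR with a beta-actin reference and MeRIP-qPCR with a U6
reference and input calibrator) and the LC-MS modification percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import MatureTRNA

__all__ = [
    "EXPRESSED_RPKM_THRESHOLD",
    "QpcrRecord",
    "count_trna_reads",
    "rpkm",
    "expression_fold_change",
    "relative_expression_ddct",
    "modification_fraction",
    "write_expression_table",
]

logger = logging.getLogger(__name__)

EXPRESSED_RPKM_THRESHOLD = 10_000.0   # strict >, per-condition RPKM filter


class NormalizationError(ValueError):
    """Raised when a library cannot be normalized (zero total, zero length)."""


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target and reference-gene Ct in one sample."""

    sample_id: str
    target_ct: float
    reference_ct: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.target_ct) and np.isfinite(self.reference_ct)):
            raise ValueError(f"non-finite Ct in sample {self.sample_id!r}")
        if self.target_ct <= 0 or self.reference_ct <= 0:
            raise ValueError(f"Ct values must be positive in sample {self.sample_id!r}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def count_trna_reads(
    hits: pd.DataFrame,
    reference: Sequence[MatureTRNA] | Mapping[str, int],
) -> pd.DataFrame:
    """Apply the best-score + mature-exclusivity counting policy.

    ``hits`` columns: read_id, target, score, target_class ('mature' or
    'genomic').  Reads whose best-score hits are exclusively genomic are not
    counted; reads with zero hits are simply absent.  Returns a table
    (trna_id, read_count, length_nt) over the full reference (zero-count
    tRNAs included).
    """
    lengths = (
        {m.trna_id: m.length for m in reference}
        if not isinstance(reference, Mapping)
        else {k: int(v) for k, v in reference.items()}
    )
    required = {"read_id", "target", "score", "target_class"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hit table needs columns {sorted(required)}")

    counts = pd.Series(0.0, index=pd.Index(sorted(lengths), name="trna_id"))
    dropped_genomic_only = 0
    if len(hits):
        best = hits["score"] == hits.groupby("read_id")["score"].transform("max")
        surv = hits.loc[best]
        mature = surv[surv["target_class"] == "mature"]
        unknown = set(mature["target"]) - set(lengths)
        if unknown:
            raise ValueError(f"hits reference unknown mature tRNAs: {sorted(unknown)[:5]}")
        n_reads_total = surv["read_id"].nunique()
        dropped_genomic_only = n_reads_total - mature["read_id"].nunique()
        if len(mature):
            k = mature.groupby("read_id")["target"].transform("size")
            weights = 1.0 / k
            per_trna = weights.groupby(mature["target"]).sum()
            counts = counts.add(per_trna, fill_value=0.0)
    if dropped_genomic_only:
        logger.info("count_trna_reads: %d reads had only genomic best hits (not counted)", dropped_genomic_only)
    out = counts.reset_index()
    out.columns = ["trna_id", "read_count"]
    out["length_nt"] = out["trna_id"].map(lengths)
    return out


def rpkm(
    counts: pd.DataFrame,
    condition: str = "",
    expressed_threshold: float = EXPRESSED_RPKM_THRESHOLD,
) -> pd.DataFrame:
    """RPKM = count / (length/1000 * total/1e6); 'expressed' iff RPKM > threshold."""
    total = float(counts["read_count"].sum())
    if total <= 0:
        raise NormalizationError("zero total counted reads; cannot compute RPKM")
    if (counts["length_nt"] <= 0).any():
        raise NormalizationError("non-positive tRNA length in count table")
    out = counts.copy()
    out["rpkm"] = out["read_count"] / ((out["length_nt"] / 1000.0) * (total / 1e6))
    out["expressed"] = out["rpkm"] > expressed_threshold
    if condition:
        out["condition"] = condition
    return out


def expression_fold_change(
    kd: pd.DataFrame,
    ctrl: pd.DataFrame,
    m7g_trnas: Iterable[str] = (),
    restrict_to_expressed: bool = True,
) -> pd.DataFrame:
    """Per-tRNA fold change FC = RPKM_kd / RPKM_ctrl with m7G class labels.

    The analysis set is defined by the expressed flag of the CONTROL
    condition (so knockdown-induced losses are not filtered away); tRNAs
    with zero control RPKM are flagged and their FC omitted (NaN).
    """
    m7g = set(m7g_trnas)
    merged = ctrl.set_index("trna_id")[["rpkm", "expressed"]].join(
        kd.set_index("trna_id")[["rpkm"]], lsuffix="_ctrl", rsuffix="_kd", how="inner"
    )
    merged.columns = ["rpkm_ctrl", "expressed_ctrl", "rpkm_kd"]
    if restrict_to_expressed:
        merged = merged[merged["expressed_ctrl"]]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = merged["rpkm_kd"] / merged["rpkm_ctrl"]
    fc[merged["rpkm_ctrl"] == 0] = np.nan
    out = pd.DataFrame(
        {
            "rpkm_ctrl": merged["rpkm_ctrl"],
            "rpkm_kd": merged["rpkm_kd"],
            "fold_change": fc,
            "m7g_class": ["m7G" if t in m7g else "non-m7G" for t in merged.index],
        }
    )
    out.index.name = "trna_id"
    return out.reset_index()


def relative_expression_ddct(test: QpcrRecord, calibrator: QpcrRecord) -> float:
    """2^-ddCt relative quantification.

    dCt = target Ct - reference Ct within a sample; ddCt = dCt(test) -
    dCt(calibrator).  Used both for qRT-PCR (beta-actin reference) and for
    MeRIP-qPCR enrichment (U6 reference, input sample as calibrator).
    """
    ddct = test.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


def modification_fraction(peaks: Mapping[str, float], modification: str) -> float:
    """LC-MS modification percentage: 100 * area_mod / sum of all nucleoside areas."""
    if modification not in peaks:
        raise KeyError(f"modification {modification!r} not in peak table")
    if any(a < 0 for a in peaks.values()):
        raise ValueError("negative peak area")
    total = float(sum(peaks.values()))
    if total == 0:
        raise ValueError("degenerate peak table: all areas zero")
    return 100.0 * float(peaks[modification]) / total


def write_expression_table(path: str | Path, table: pd.DataFrame, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("# " + "\t".join(table.columns) + "\n")
        table.to_csv(fh, sep="\t", index=False, header=False)
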