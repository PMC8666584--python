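"""Synthetic data with the statistical structure the analyses assume.

Three generators, all pure functions of (config, seed):

* a mature tRNA reference in which a configurable fraction of tRNAs carry
  a designated m7G guanosine in the variable-loop window (positions 46-48);
* TRAC-seq read sets for a cleavage-treated and a non-treated arm, where
  each molecule of a modified tRNA is cleaved with a per-arm Bernoulli
  probability and the emitted read then starts exactly at the modified
  position (downstream fragment), otherwise at position 1;
* paired polysome/input count tables for a control and a knockdown
  condition in which a gene's true log2 translation-efficiency change is
  -beta * f + N(0, sigma), with f its m7G-codon frequency, and counts are
  drawn negative-binomially around means consistent with the true TE.

Ground truth (modified flags, implanted positions, per-gene f and true
log2 TE ratio) is returned alongside every simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.special import polygamma

from .reference import MatureTRNA, SENSE_CODONS, STOP_CODONS, revcomp

__all__ = [
    "TracSimConfig",
    "TESimConfig",
    "SimulatedTE",
    "simulate_trna_reference",
    "simulate_trac_library",
    "simulate_expression_library",
    "simulate_te_experiment",
    "expected_pearson_r",
    "write_fixtures",
]

_LN2_SQ = np.log(2.0) ** 2
_ARM_STREAM = {"treated": 1, "non_treated": 2}
_CONDITION_STREAM = {"control": 3, "knockdown": 4}

# Codons decoded by a panel of tRNAs commonly found m7G-modified
# (e.g. Lys-CTT -> AAG, Cys-GCA -> TGC); default target set for the
# translation simulation when no discovered codon set is supplied.
DEFAULT_M7G_CODONS = ("AAG", "TGC", "AGA", "GGC", "GCT", "GTG", "CCT")


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class TracSimConfig:
    """Conditions for the TRAC-seq simulation.

    ``p_cleave_treated`` / ``p_cleave_background`` are per-molecule cleavage
    probabilities (background applies to the non-treated arm and to
    unmodified tRNAs in either arm).  ``m7g_position`` fixes the implanted
    site; ``None`` draws it uniformly from 46-48 per modified tRNA.

    Defaults emulate the repertoire scale of a human cell line: a few
    hundred distinct mature tRNA species of which 17 carry m7G.
    """

    n_trnas: int = 300
    reads_per_trna: int = 2000
    modified_fraction: float = 17 / 300
    m7g_position: int | None = None
    p_cleave_treated: float = 0.3
    p_cleave_background: float = 0.01
    read_length: int | None = None
    length_range: tuple[int, int] = (70, 90)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trnas < 1:
            raise ConfigError("n_trnas must be >= 1")
        if self.reads_per_trna < 1:
            raise ConfigError("reads_per_trna must be >= 1")
        if not 0.0 <= self.modified_fraction <= 1.0:
            raise ConfigError("modified_fraction must lie in [0, 1]")
        if not 0.0 <= self.p_cleave_background < 1.0 or not 0.0 <= self.p_cleave_treated <= 1.0:
            raise ConfigError("cleavage probabilities must lie in [0, 1]")
        if self.p_cleave_background > self.p_cleave_treated:
            raise ConfigError("p_cleave_background must not exceed p_cleave_treated")
        if self.m7g_position is not None and self.m7g_position not in (46, 47, 48):
            raise ConfigError("m7g_position must be in {46, 47, 48}")
        lo, hi = self.length_range
        if not (49 <= lo <= hi):
            raise ConfigError("length_range must satisfy 49 <= lo <= hi")


def _random_anticodon(rng: np.random.Generator, forbid_stop_codon: bool) -> str:
    bases = np.array(list("ACGT"))
    while True:
        ac = "".join(rng.choice(bases, size=3))
        if not forbid_stop_codon or revcomp(ac) not in STOP_CODONS:
            return ac


def simulate_trna_reference(config: TracSimConfig) -> tuple[list[MatureTRNA], pd.DataFrame]:
    """Simulate mature tRNAs (70-90 nt incl. CCA) with random anticodons.

    The first ``round(modified_fraction * n_trnas)`` tRNAs carry a G at
    their designated m7G position.  Modified tRNAs are given anticodons
    whose Watson-Crick codon is a sense codon, so a decoded-codon set built
    from them is usable for CDS simulation.  Returns the reference and a
    truth table (trna_id, modified, m7g_position, anticodon, length).
    """
    rng = np.random.default_rng([config.seed, 0])
    n_mod = int(round(config.modified_fraction * config.n_trnas))
    bases = np.array(list("ACGT"))
    matures: list[MatureTRNA] = []
    rows = []
    for i in range(config.n_trnas):
        modified = i < n_mod
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        body = rng.choice(bases, size=length - 3)
        anticodon = _random_anticodon(rng, forbid_stop_codon=modified)
        body[33:36] = list(anticodon)  # anticodon loop at mature positions 34-36
        if modified:
            pos = config.m7g_position or int(rng.integers(46, 49))
            body[pos - 1] = "G"
        else:
            pos = None
        seq = "".join(body) + "CCA"
        aa = str(Seq(revcomp(anticodon)).translate())
        trna_id = f"tRNA-{aa}-{anticodon}-{i + 1}"
        matures.append(MatureTRNA(trna_id=trna_id, sequence=seq, anticodon=anticodon, isotype=aa))
        rows.append(
            {
                "trna_id": trna_id,
                "modified": modified,
                "m7g_position": pos if pos is not None else pd.NA,
                "anticodon": anticodon,
                "length": length,
            }
        )
    truth = pd.DataFrame(rows).astype({"m7g_position": "Int64"})
    return matures, truth


def simulate_trac_library(
    reference: Sequence[MatureTRNA],
    truth: pd.DataFrame,
    config: TracSimConfig,
    arm: str,
    emit_reads: bool = True,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emit one TRAC-seq library: FASTQ records and a ready alignment table.

    Per molecule of a modified tRNA, with per-arm probability p the molecule
    is cleaved and its read starts at the m7G position; otherwise the read
    starts at position 1.  Unmodified tRNAs cleave only at the background
    rate, at a uniformly random internal position.  Returns
    (fastq_records as (id, seq, qual) tuples, alignment table with 1-based
    inclusive trna_id/start/end columns).  ``emit_reads=False`` skips the
    sequence records (the alignment table alone drives the pileup stage).
    """
    if arm not in _ARM_STREAM:
        raise ConfigError(f"unknown arm {arm!r} (expected 'treated' or 'non_treated')")
    rng = np.random.default_rng([config.seed, _ARM_STREAM[arm]])
    p_site = config.p_cleave_treated if arm == "treated" else config.p_cleave_background
    info = truth.set_index("trna_id")
    records: list[tuple[str, str, str]] = []
    tables = []
    for m in reference:
        n = config.reads_per_trna
        length = m.length
        modified = bool(info.loc[m.trna_id, "modified"])
        if modified:
            site = int(info.loc[m.trna_id, "m7g_position"])
            cleaved = rng.random(n) < p_site
            start = np.where(cleaved, site, 1)
        else:
            cleaved = rng.random(n) < config.p_cleave_background
            start = np.where(cleaved, rng.integers(2, length, size=n), 1)
        end = np.full(n, length)
        if config.read_length is not None:
            end = np.minimum(start + config.read_length - 1, length)
        ids = [f"{m.trna_id}:{arm}:{j}" for j in range(n)]
        if emit_reads:
            for rid, s, e in zip(ids, start, end):
                frag = m.sequence[s - 1 : e]
                records.append((rid, frag, "I" * len(frag)))
        tables.append(pd.DataFrame({"read_id": ids, "trna_id": m.trna_id, "start": start, "end": end}))
    alignments = pd.concat(tables, ignore_index=True)
    return records, alignments


def simulate_expression_library(
    reference: Sequence[MatureTRNA],
    truth: pd.DataFrame,
    condition: str,
    n_reads: int = 200_000,
    knockdown_factor: float = 0.6,
    genomic_tie_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an ALKB-treated tRNA expression library as a read hit table.

    Per-tRNA abundances are log-normal and shared between conditions; in the
    knockdown condition the abundances of m7G-modified tRNAs are scaled by
    ``knockdown_factor``.  A ``genomic_tie_fraction`` of reads additionally
    carry an equal-score genomic-locus hit, exercising the exclusive-mapping
    rule.  Returns columns (read_id, target, score, target_class).
    """
    if condition not in _CONDITION_STREAM:
        raise ConfigError(f"unknown condition {condition!r}")
    abundance_rng = np.random.default_rng([seed, 7])
    weights = abundance_rng.lognormal(mean=0.0, sigma=1.0, size=len(reference))
    modified = truth.set_index("trna_id")["modified"]
    if condition == "knockdown":
        scale = np.array([knockdown_factor if modified.loc[m.trna_id] else 1.0 for m in reference])
        weights = weights * scale
    rng = np.random.default_rng([seed, _CONDITION_STREAM[condition]])
    counts = rng.multinomial(n_reads, weights / weights.sum())
    targets = np.repeat([m.trna_id for m in reference], counts)
    read_ids = np.array([f"{condition}:r{j}" for j in range(n_reads)])
    hits = pd.DataFrame(
        {"read_id": read_ids, "target": targets, "score": 0, "target_class": "mature"}
    )
    tie = rng.random(n_reads) < genomic_tie_fraction
    genomic = hits.loc[tie].assign(
        target=lambda d: "locus_" + d["target"], target_class="genomic"
    )
    return pd.concat([hits, genomic], ignore_index=True)


# ---------------------------------------------------------------------------
# Translation-efficiency experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TESimConfig:
    """Conditions for the paired polysome/input simulation.

    ``beta`` is the log2 TE decrease per unit m7G-codon frequency under
    knockdown; ``sigma`` the gene-level noise SD on the true log2 TE ratio;
    ``dispersion`` the NB dispersion (variance = mu + dispersion * mu^2).
    """

    n_genes: int = 8000
    cds_length_range: tuple[int, int] = (100, 500)
    codon_freq_range: tuple[float, float] = (0.0, 0.5)
    beta: float = 2.0
    sigma: float = 0.2
    dispersion: float = 0.1
    library_size: float = 2e7
    m7g_codons: tuple[str, ...] = DEFAULT_M7G_CODONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        lo, hi = self.cds_length_range
        if not (1 <= lo < hi):
            raise ConfigError("cds_length_range must be a non-degenerate codon-count interval")
        flo, fhi = self.codon_freq_range
        if not (0.0 <= flo < fhi <= 1.0):
            raise ConfigError("codon_freq_range must be a non-degenerate interval in [0, 1]")
        if self.beta < 0 or self.sigma < 0 or self.dispersion < 0:
            raise ConfigError("beta, sigma, dispersion must be >= 0")
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        bad = [c for c in self.m7g_codons if c in STOP_CODONS or len(c) != 3]
        if bad or not self.m7g_codons:
            raise ConfigError(f"m7g_codons must be non-empty sense codons (bad: {bad})")


@dataclass
class SimulatedTE:
    cds: dict[str, str]
    counts: pd.DataFrame        # gene x {input_ctrl, input_kd, poly_ctrl, poly_kd}
    lengths: pd.Series          # CDS length in nt
    truth: pd.DataFrame         # gene_id, f, log2_te_ratio_true
    config: TESimConfig


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_te_experiment(config: TESimConfig) -> SimulatedTE:
    """Simulate CDSs and four count tables with implanted codon-dependent TE.

    Each CDS mixes codons from the m7G codon set with non-set sense codons
    so that its realized m7G-codon frequency f equals the truth table
    exactly; the true log2 TE ratio is -beta*f + N(0, sigma); counts are
    NB draws around library-size-scaled means consistent with the true TE.
    """
    rng = np.random.default_rng([config.seed, 10])
    n = config.n_genes
    lo, hi = config.cds_length_range
    n_codons = rng.integers(lo, hi + 1, size=n)
    f_target = rng.uniform(*config.codon_freq_range, size=n)
    k_set = np.rint(f_target * n_codons).astype(np.int64)
    f_true = k_set / n_codons

    set_codons = np.array(config.m7g_codons)
    other_codons = np.array([c for c in SENSE_CODONS if c not in config.m7g_codons])
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    cds: dict[str, str] = {}
    for gid, nc, k in zip(gene_ids, n_codons, k_set):
        codons = np.concatenate(
            [rng.choice(set_codons, size=k), rng.choice(other_codons, size=nc - k)]
        )
        rng.shuffle(codons)
        cds[gid] = "".join(codons)

    log2_ratio_true = -config.beta * f_true + rng.normal(0.0, config.sigma, size=n)
    te_ctrl = np.ones(n)
    te_kd = 2.0 ** log2_ratio_true

    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    length_nt = 3 * n_codons
    w = abundance * (length_nt / 1000.0)
    L = config.library_size
    mu = {
        "input_ctrl": L * w / w.sum(),
        "input_kd": L * w / w.sum(),
        "poly_ctrl": L * (w * te_ctrl) / (w * te_ctrl).sum(),
        "poly_kd": L * (w * te_kd) / (w * te_kd).sum(),
    }
    counts = pd.DataFrame(
        {lib: _nb_draw(rng, m, config.dispersion) for lib, m in mu.items()},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "f": f_true, "log2_te_ratio_true": log2_ratio_true}
    )
    lengths = pd.Series(length_nt, index=counts.index, name="length_nt")
    return SimulatedTE(cds=cds, counts=counts, lengths=lengths, truth=truth, config=config)


def expected_pearson_r(config: TESimConfig) -> float:
    """Closed-form Pearson r between f and measured log2 TE ratio.

    Under the generative model, measured log2 TR = -beta*f + e + m with
    e ~ N(0, sigma^2) and m the count-measurement noise summed over the four
    libraries.  For NB counts with mean mu and dispersion phi, the
    log-count variance is trigamma(1/phi) + E[1/mu] (Gamma-Poisson mixture;
    delta method for the Poisson layer), giving

        r = -beta * sd(f) / sqrt(beta^2 var(f) + sigma^2 + var_m)

    with var(f) = (f_hi - f_lo)^2 / 12 for the uniform frequency draw.
    """
    flo, fhi = config.codon_freq_range
    var_f = (fhi - flo) ** 2 / 12.0
    mean_count = config.library_size / config.n_genes
    # E[1/mu] over lognormal(0,1) abundance weights: E[w] * E[1/w] = e
    inv_mu = np.e / mean_count
    per_lib = (polygamma(1, 1.0 / config.dispersion) if config.dispersion > 0 else 0.0) + inv_mu
    var_m = 4.0 * per_lib / _LN2_SQ
    denom = np.sqrt(config.beta**2 * var_f + config.sigma**2 + var_m)
    if denom == 0:
        return 0.0
    return float(-config.beta * np.sqrt(var_f) / denom)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def _write_fastq(path: Path, records: Sequence[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _write_fasta(path: Path, items: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in items.items():
            fh.write(f">{name}\n{seq}\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(
    outdir: str | Path,
    trac_config: TracSimConfig | None = None,
    te_config: TESimConfig | None = None,
) -> dict:
    """Write FASTA/FASTQ/TSV fixtures plus a JSON manifest with file hashes,
    seeds and truth-table paths.  Byte-identical on rerun with one config."""
    from .reference import write_reference_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trac_config = trac_config or TracSimConfig()
    te_config = te_config or TESimConfig()
    files: dict[str, str] = {}

    reference, trna_truth = simulate_trna_reference(trac_config)
    write_reference_fasta(reference, outdir / "mature_trnas.fasta")
    files["reference_fasta"] = "mature_trnas.fasta"
    realized = []
    for arm in ("treated", "non_treated"):
        records, aln = simulate_trac_library(reference, trna_truth, trac_config, arm)
        _write_fastq(outdir / f"trac_{arm}.fastq", records)
        aln.to_csv(outdir / f"trac_{arm}.alignments.tsv", sep="\t", index=False)
        files[f"trac_{arm}_fastq"] = f"trac_{arm}.fastq"
        files[f"trac_{arm}_alignments"] = f"trac_{arm}.alignments.tsv"
        mod = trna_truth[trna_truth["modified"]]
        for _, row in mod.iterrows():
            sub = aln[aln["trna_id"] == row["trna_id"]]
            frac = float((sub["start"] == row["m7g_position"]).mean())
            realized.append({"trna_id": row["trna_id"], "arm": arm, "realized_cleaved_fraction": frac})
    trna_truth.to_csv(outdir / "trna_truth.tsv", sep="\t", index=False)
    pd.DataFrame(realized).to_csv(outdir / "realized_cleavage.tsv", sep="\t", index=False)
    files["trna_truth"] = "trna_truth.tsv"
    files["realized_cleavage"] = "realized_cleavage.tsv"

    for condition in ("control", "knockdown"):
        hits = simulate_expression_library(reference, trna_truth, condition, seed=trac_config.seed)
        hits.to_csv(outdir / f"expression_{condition}.hits.tsv", sep="\t", index=False)
        files[f"expression_{condition}_hits"] = f"expression_{condition}.hits.tsv"

    sim = simulate_te_experiment(te_config)
    _write_fasta(outdir / "cds.fasta", sim.cds)
    sim.counts.to_csv(outdir / "te_counts.tsv", sep="\t")
    sim.truth.to_csv(outdir / "te_truth.tsv", sep="\t", index=False)
    files["cds_fasta"] = "cds.fasta"
    files["te_counts"] = "te_counts.tsv"
    files["te_truth"] = "te_truth.tsv"

    manifest = {
        "trac_config": asdict(trac_config),
        "te_config": asdict(te_config),
        "files": files,
        "sha256": {name: _sha256(outdir / rel) for name, rel in files.items()},
        "truth_tables": ["trna_truth.tsv", "te_truth.tsv"],
        "n_truth_rows": int(len(trna_truth) + len(sim.truth)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
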