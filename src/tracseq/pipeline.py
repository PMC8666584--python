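"""End-to-end orchestration: simulate -> TRAC calling -> expression -> TE.

A run executes the full synthetic study: a mature tRNA reference with
implanted m7G sites; cleavage-treated and non-treated TRAC-seq libraries
for a control and a METTL1-knockdown-like condition (knockdown scales the
cleavage probability down); ALKB-treated expression libraries with the
modified-tRNA abundances scaled down under knockdown; and the paired
polysome/input experiment whose m7G codon set is, by default, the set
*discovered* by the TRAC caller, so the whole measurement stack is
exercised end to end.  All stages are pure functions of the config; every
output carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import trac
from .expression import count_trna_reads, expression_fold_change, rpkm, write_expression_table
from .reference import build_m7g_codon_set, write_reference_fasta, write_reference_table
from .simulate import (
    TESimConfig,
    TracSimConfig,
    expected_pearson_r,
    simulate_expression_library,
    simulate_te_experiment,
    simulate_trac_library,
    simulate_trna_reference,
)
from .translation import (
    MIN_INPUT_FPKM_DEFAULT,
    QUANTILE_DEFAULT,
    TE_THRESHOLD_DEFAULT,
    classify_te_genes,
    codon_profiles,
    compare_groups,
    correlate_freq_te,
    fpkm,
    split_by_codon_frequency,
    te_class_codon_profile,
    translation_efficiency,
    translation_ratio,
)

__all__ = ["RunConfig", "PlanError", "run_pipeline", "report_summary"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "trac", "expression", "translation")


class PlanError(ValueError):
    """Raised before any computation when enabled stages miss a dependency."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a full synthetic run."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    trac_sim: TracSimConfig = field(default_factory=TracSimConfig)
    te_sim: TESimConfig = field(default_factory=TESimConfig)
    # knockdown condition: cleavage probability scaled by this factor
    knockdown_cleave_factor: float = 0.5
    # expression libraries
    expression_reads: int = 200_000
    expression_knockdown_factor: float = 0.6
    # analysis thresholds
    min_depth: int = trac.MIN_DEPTH_DEFAULT
    epsilon: float = trac.EPSILON_DEFAULT
    te_threshold: float = TE_THRESHOLD_DEFAULT
    quantile: float = QUANTILE_DEFAULT
    min_input_fpkm: float = MIN_INPUT_FPKM_DEFAULT
    # couple the TE simulation to the codon set discovered by the caller
    use_discovered_codon_set: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PlanError(f"unknown stages {sorted(unknown)}")
        deps = {"trac": "simulate", "expression": "simulate", "translation": "simulate"}
        for stage, dep in deps.items():
            if stage in self.stages and dep not in self.stages:
                raise PlanError(f"stage {stage!r} requires stage {dep!r}")
        # seed propagates into the simulation configs unless they were set explicitly
        if self.trac_sim.seed != self.seed:
            object.__setattr__(self, "trac_sim", dataclasses.replace(self.trac_sim, seed=self.seed))
        if self.te_sim.seed != self.seed:
            object.__setattr__(self, "te_sim", dataclasses.replace(self.te_sim, seed=self.seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "trac_sim" in d:
            d["trac_sim"] = TracSimConfig(**{**d["trac_sim"],
                                             "length_range": tuple(d["trac_sim"].get("length_range", (70, 90)))})
        if "te_sim" in d:
            te = dict(d["te_sim"])
            for k in ("cds_length_range", "codon_freq_range", "m7g_codons"):
                if k in te:
                    te[k] = tuple(te[k])
            d["te_sim"] = TESimConfig(**te)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _score_tracks_for_condition(reference, truth, sim_config, min_depth, epsilon):
    """Simulate both arms of one condition and compute per-tRNA score tracks."""
    pileups = {}
    profiles = {}
    for arm in ("treated", "non_treated"):
        _, aln = simulate_trac_library(reference, truth, sim_config, arm, emit_reads=False)
        pl = trac.compute_pileup(aln, reference, arm=arm)
        pileups[arm] = {p.trna_id: p for p in pl}
        profiles[arm] = {p.trna_id: trac.cleavage_ratio(p, min_depth=min_depth) for p in pl}
    tracks = {
        tid: trac.cleavage_score(profiles["treated"][tid], profiles["non_treated"][tid], epsilon=epsilon)
        for tid in profiles["treated"]
        if tid in profiles["non_treated"]
    }
    return pileups, profiles, tracks


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return the run report.

    Writes TSV/JSON outputs under ``outdir``; every file carries the config
    hash.  Re-running an unchanged config reproduces identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash}"
    report: dict = {"config_hash": config.config_hash, "stages_run": []}

    def _stage(name):
        report["stages_run"].append(name)
        return time.perf_counter()

    def _done(name, t0):
        # wall-times go to the log so report.json stays reproducible byte-for-byte
        logger.info("stage %s finished in %.2fs (config %s)", name, time.perf_counter() - t0, config.config_hash)

    reference = truth = None
    calls = []
    codon_set = None

    if "simulate" in config.stages:
        t0 = _stage("simulate")
        reference, truth = simulate_trna_reference(config.trac_sim)
        write_reference_fasta(reference, outdir / "mature_trnas.fasta")
        write_reference_table(reference, outdir / "reference.tsv")
        truth.to_csv(outdir / "trna_truth.tsv", sep="\t", index=False)
        report["n_trnas"] = len(reference)
        report["n_modified_truth"] = int(truth["modified"].sum())
        _done("simulate", t0)

    if "trac" in config.stages:
        t0 = _stage("trac")
        kd_sim = dataclasses.replace(
            config.trac_sim,
            p_cleave_treated=config.trac_sim.p_cleave_treated * config.knockdown_cleave_factor,
            seed=config.trac_sim.seed + 1,
        )
        pil_c, prof_c, tracks_ctrl = _score_tracks_for_condition(
            reference, truth, config.trac_sim, config.min_depth, config.epsilon
        )
        _, _, tracks_kd = _score_tracks_for_condition(
            reference, truth, kd_sim, config.min_depth, config.epsilon
        )
        calls = [
            c
            for tid in sorted(tracks_ctrl)
            for c in trac.call_m7g_sites(tracks_ctrl[tid], prof_c["treated"][tid])
        ]
        trac.write_site_track(
            outdir / "site_track.tsv",
            pil_c["treated"], pil_c["non_treated"],
            prof_c["treated"], prof_c["non_treated"],
            tracks_ctrl, header_extra=tag,
        )
        trac.write_calls(outdir / "m7g_calls.tsv", calls, header_extra=tag)
        called_ids = sorted({c.trna_id for c in calls})
        report["n_m7g_trnas_called"] = len(called_ids)
        report["m7g_trnas"] = called_ids
        if called_ids:
            lv_ctrl = trac.methylation_levels({t: tracks_ctrl[t] for t in called_ids}, condition="control")
            lv_kd = trac.methylation_levels({t: tracks_kd[t] for t in called_ids}, condition="knockdown")
            try:
                w, p = trac.compare_methylation_paired(lv_ctrl, lv_kd)
                report["methylation_wilcoxon"] = {"W": w, "p_value": p}
            except ValueError as exc:
                report["methylation_wilcoxon"] = {"error": str(exc)}
            motif = trac.site_motif(calls, reference, flank=5)
            motif.to_csv(outdir / "site_motif.tsv", sep="\t")
            codon_set = build_m7g_codon_set(calls, reference)
            report["m7g_codon_set"] = sorted(codon_set.codons)
        else:
            report["methylation_wilcoxon"] = {"skipped": "no m7G calls"}
            report["m7g_codon_set"] = []
        _done("trac", t0)

    if "expression" in config.stages:
        t0 = _stage("expression")
        tables = {}
        for condition in ("control", "knockdown"):
            hits = simulate_expression_library(
                reference, truth, condition,
                n_reads=config.expression_reads,
                knockdown_factor=config.expression_knockdown_factor,
                seed=config.seed,
            )
            counts = count_trna_reads(hits, reference)
            tables[condition] = rpkm(counts, condition=condition)
            write_expression_table(outdir / f"expression_{condition}.tsv", tables[condition], header_extra=tag)
        m7g_ids = set(report.get("m7g_trnas", [])) or set(truth.loc[truth["modified"], "trna_id"])
        fc = expression_fold_change(tables["knockdown"], tables["control"], m7g_trnas=m7g_ids)
        write_expression_table(outdir / "expression_fold_change.tsv", fc, header_extra=tag)
        med = fc.groupby("m7g_class")["fold_change"].median()
        report["expression_fold_change_median"] = {k: float(v) for k, v in med.items()}
        _done("expression", t0)

    if "translation" in config.stages:
        t0 = _stage("translation")
        te_sim = config.te_sim
        if config.use_discovered_codon_set and codon_set is not None and codon_set.codons:
            te_sim = dataclasses.replace(te_sim, m7g_codons=tuple(sorted(codon_set.codons)))
        if config.use_discovered_codon_set and (codon_set is None or not codon_set.codons):
            report["translation"] = {"skipped": "empty discovered codon set"}
        else:
            sim = simulate_te_experiment(te_sim)
            fpkms = fpkm(sim.counts, sim.lengths)
            te_ctrl = translation_efficiency(fpkms["poly_ctrl"], fpkms["input_ctrl"], config.min_input_fpkm)
            te_kd = translation_efficiency(fpkms["poly_kd"], fpkms["input_kd"], config.min_input_fpkm)
            tr = translation_ratio(te_kd, te_ctrl)
            f = codon_profiles(sim.cds, te_sim.m7g_codons)
            r, p = correlate_freq_te(f, tr["log2_translation_ratio"])
            low, high = split_by_codon_frequency(f, q=config.quantile)
            ratios = tr["translation_ratio"]
            cmp_groups = compare_groups(
                ratios.reindex(low).dropna(), ratios.reindex(high).dropna(),
                label_a="low_f", label_b="high_f",
            )
            classes = classify_te_genes(tr["log2_translation_ratio"], threshold=config.te_threshold)
            class_mean_f = f.groupby(classes).mean()
            profile = te_class_codon_profile(classes, sim.cds, te_sim.m7g_codons)
            per_gene = pd.DataFrame(
                {
                    "input_fpkm_ctrl": fpkms["input_ctrl"], "input_fpkm_kd": fpkms["input_kd"],
                    "poly_fpkm_ctrl": fpkms["poly_ctrl"], "poly_fpkm_kd": fpkms["poly_kd"],
                    "te_ctrl": te_ctrl, "te_kd": te_kd,
                }
            ).join(tr).join(f).join(classes)
            with open(outdir / "te_genes.tsv", "w") as fh:
                fh.write(f"# {tag}\n# gene_id\t" + "\t".join(per_gene.columns) + "\n")
                per_gene.to_csv(fh, sep="\t", header=False)
            profile.to_csv(outdir / "te_decreased_codon_profile.tsv", sep="\t", index=False)
            report["translation"] = {
                "pearson_r": r,
                "pearson_p": p,
                "expected_pearson_r": expected_pearson_r(te_sim),
                "group_comparison": asdict(cmp_groups),
                "te_class_sizes": classes.value_counts().to_dict(),
                "te_class_mean_f": {k: float(v) for k, v in class_mean_f.items()},
            }
        _done("translation", t0)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def report_summary(report: dict) -> str:
    """Human-readable one-page summary of a run report."""
    lines = [f"tracseq run (config {report.get('config_hash', '?')})"]
    if "n_m7g_trnas_called" in report:
        lines.append(f"  m7G-modified tRNAs called: {report['n_m7g_trnas_called']}")
        lines.append(f"  m7G codon set: {', '.join(report.get('m7g_codon_set', [])) or '(empty)'}")
    else:
        lines.append("  TRAC stage skipped")
    if "methylation_wilcoxon" in report:
        mw = report["methylation_wilcoxon"]
        if "p_value" in mw:
            lines.append(f"  methylation control vs knockdown: W={mw['W']:.1f}, p={mw['p_value']:.3g}")
    if "expression_fold_change_median" in report:
        med = report["expression_fold_change_median"]
        parts = ", ".join(f"{k}: {v:.3f}" for k, v in sorted(med.items()))
        lines.append(f"  median expression fold change ({parts})")
    else:
        lines.append("  expression stage skipped")
    tr = report.get("translation")
    if isinstance(tr, dict) and "pearson_r" in tr:
        lines.append(
            f"  Pearson r(f, log2 TR) = {tr['pearson_r']:.3f} "
            f"(model closed form {tr['expected_pearson_r']:.3f}), p = {tr['pearson_p']:.3g}"
        )
        g = tr["group_comparison"]
        lines.append(
            f"  low-f vs high-f translation ratio: U={g['statistic']:.0f}, p={g['p_value']:.3g} ({g['direction']})"
        )
        sizes = tr["te_class_sizes"]
        lines.append(
            "  TE classes: " + ", ".join(f"{k}={v}" for k, v in sorted(sizes.items()))
        )
    elif isinstance(tr, dict):
        lines.append(f"  translation stage skipped ({tr.get('skipped', '?')})")
    else:
        lines.append("  translation stage skipped")
    return "\n".join(lines)
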