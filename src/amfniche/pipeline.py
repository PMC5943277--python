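"""Pipeline orchestration: read processing -> classification -> tracking ->
ecological statistics, driven by a serializable config.

``make_demo`` materializes a complete synthetic study (reference FASTA,
per-sample paired FASTQ, metadata and dilution-series TSV, ground-truth
manifest) and ``run_pipeline`` runs every stage over such a directory,
writing TSV/JSON artifacts.  All randomness fans out from a single seed,
and no output embeds wall-clock state, so re-running a config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classify, ecostats, mpn, readproc, synth, tracking

__all__ = ["PipelineConfig", "run_pipeline", "make_demo", "DEMO_SYNTH"]

# demo study: full 3-trial x 4-block design, sized to run in minutes on one CPU
DEMO_SYNTH = synth.SynthConfig(reads_per_sample=800)
DEMO_DEPTH = 500


def demo_pipeline_config(fixture_dir, output_dir, seed: int = 0,
                         n_perm: int = 999) -> "PipelineConfig":
    """Pipeline config matching the demo fixture scale."""
    return PipelineConfig(input_dir=str(fixture_dir), output_dir=str(output_dir),
                          rarefaction_depth=DEMO_DEPTH, n_perm=n_perm, seed=seed)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full pipeline run.

    The threshold defaults are the study criteria: QV 30 3' trimming,
    200 nt length floor, overlap window [10, 300] nt, E-value 1e-100,
    95% identity, 330 bp (AM) / 220 bp (outgroup) alignment length, and
    rarefaction to 10,000 reads per sample.
    """

    input_dir: str = "."
    output_dir: str = "out"
    inoculum_sample: str = "inoculum"
    qv_threshold: int = 30
    min_length: int = 200
    min_overlap: int = 10
    max_overlap: int = 300
    max_mismatch_rate: float = 0.1
    adapter: Optional[str] = None
    min_identity: float = 0.95
    min_len_am: int = 330
    min_len_out: int = 220
    max_evalue: float = 1e-100
    rarefaction_depth: int = 10000
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")
        if self.rarefaction_depth <= 0 or self.min_length <= 0:
            raise ValueError("depth and min_length must be positive")
        if self.min_overlap > self.max_overlap:
            raise ValueError("min_overlap must be <= max_overlap")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed from the global seed."""
        import zlib
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))


def make_demo(out_dir, seed: int = 0,
              config: Optional[synth.SynthConfig] = None) -> Path:
    """Write a complete synthetic study into ``out_dir``.

    Produces reference.fasta, reads/<sample>_R{1,2}.fastq, metadata.tsv,
    dilution_series.tsv, ground truth TSVs, the synth config as YAML, and
    a manifest.json of ground-truth summary values for assertions.
    """
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    cfg = config or DEMO_SYNTH
    cfg = dataclasses.replace(cfg, seed=seed)
    ref = synth.make_reference(cfg)
    design = synth.make_design(cfg)
    reads, truth = synth.make_reads(cfg, ref, design)
    dil = synth.make_dilution_series(cfg)

    (out / "reference.fasta").write_text(ref.to_fasta())
    design.to_csv(out / "metadata.tsv", sep="\t", index=False)
    dil.to_csv(out / "dilution_series.tsv", sep="\t", index=False)
    truth.proportions.to_csv(out / "true_proportions.tsv", sep="\t")
    (out / "synth_config.yaml").write_text(synth.config_to_yaml(cfg))
    for sid, rs in reads.items():
        synth.write_fastq_pair(rs, out / "reads" / f"{sid}_R1.fastq",
                               out / "reads" / f"{sid}_R2.fastq")
    share_by_trial = (design[design["inoculated"]]
                      .groupby("trial")["true_inoculum_share"].mean())
    manifest = {
        "seed": seed,
        "samples": sorted(reads),
        "inoculum_otus": synth.inoculum_otu_ids(cfg),
        "true_mean_inoculated_share_by_trial": {
            k: float(v) for k, v in share_by_trial.items()},
        "true_propagule_density": truth.propagule_density,
        "yield_coefficients": truth.yield_coefficients,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _log(lines, msg):
    lines.append(msg)
    print(msg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage over ``config.input_dir``; returns the result bundle.

    Stages: trim+merge each sample's FASTQ pair; classify merged reads
    against the reference; build and rarefy the OTU table; define the
    inoculum OTU set from the inoculum sample and track its share; compute
    yield responses, commonness, robustness, Bray-Curtis PERMANOVA, the
    stepwise linear regression of yield response and the block-random
    logistic regression of tracked reads; estimate per-trial MPNs.
    Artifacts are TSV/JSON under ``config.output_dir``.
    """
    ind = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = []
    (out / "config.yaml").write_text(config.to_yaml())

    reference = synth.ReferenceSet.from_fasta(ind / "reference.fasta")
    metadata = pd.read_csv(ind / "metadata.tsv", sep="\t")
    samples = list(metadata["sample_id"])
    if (ind / "reads" / f"{config.inoculum_sample}_R1.fastq").exists():
        samples.append(config.inoculum_sample)

    criteria = classify.AssignmentCriteria(
        max_evalue=config.max_evalue, min_identity=config.min_identity,
        min_len_am=config.min_len_am, min_len_out=config.min_len_out)

    assignments = {}
    readproc_rows = {}
    for sid in samples:
        r1 = ind / "reads" / f"{sid}_R1.fastq"
        r2 = ind / "reads" / f"{sid}_R2.fastq"
        if not r1.exists() or not r2.exists():
            raise FileNotFoundError(f"readproc: missing FASTQ pair for {sid}")
        merged, counts = readproc.process_sample(
            r1, r2, qv_threshold=config.qv_threshold, adapter=config.adapter,
            min_length=config.min_length, min_overlap=config.min_overlap,
            max_overlap=config.max_overlap,
            max_mismatch_rate=config.max_mismatch_rate)
        readproc_rows[sid] = counts
        assignments[sid] = classify.assign_sample(merged, reference,
                                                  criteria=criteria)
        _log(log, f"readproc+classify {sid}: input={counts['input']} "
                  f"merged={counts['merged']}")
    pd.DataFrame(readproc_rows).T.to_csv(out / "readproc_counts.tsv", sep="\t",
                                         index_label="sample_id")

    table = classify.build_otu_table(assignments)
    table.qc.to_csv(out / "classify_qc.tsv", sep="\t", index_label="sample_id")
    table.to_tsv(out / "otu_table_raw.tsv")
    rarefied = classify.rarefy(table, depth=config.rarefaction_depth,
                               seed=config.stage_seed("rarefy"))
    rarefied.to_tsv(out / "otu_table_rarefied.tsv")
    _log(log, f"classify: {table.counts.shape[0]} samples x "
              f"{table.counts.shape[1]} OTUs; rarefied to "
              f"{config.rarefaction_depth}")

    inoc_set = tracking.define_inoculum_set(rarefied, config.inoculum_sample)
    track_df = tracking.track(rarefied, inoc_set,
                              exclude_samples=[config.inoculum_sample])
    track_df.to_csv(out / "tracking.tsv", sep="\t", index_label="sample_id")
    _log(log, f"tracking: {len(inoc_set)} inoculum OTUs")

    meta = metadata[metadata["sample_id"].isin(track_df.index)].copy()
    meta = meta.merge(track_df["share"].rename("tracked_share"),
                      left_on="sample_id", right_index=True)
    meta["tracked_pct"] = 100.0 * meta["tracked_share"]

    yr = ecostats.yield_response(meta)
    yr.to_csv(out / "yield_response.tsv", sep="\t")
    comm = ecostats.commonness(rarefied, meta, exclude=inoc_set)
    comm.commonness.rename("commonness").to_csv(out / "commonness.tsv", sep="\t",
                                                index_label="otu_id")
    rob = ecostats.robustness(rarefied, meta, exclude=inoc_set)
    rob.ratios.to_csv(out / "robustness.tsv", sep="\t", index_label="otu_id")

    field_table = classify.OTUTable(
        rarefied.counts.drop(index=config.inoculum_sample, errors="ignore"),
        rarefied=True, depth=rarefied.depth)
    dist = ecostats.bray_curtis_matrix(field_table)
    perma = ecostats.permanova(
        dist, meta.set_index("sample_id"), n_perm=config.n_perm,
        seed=config.stage_seed("permanova"))
    perma.to_csv(out / "permanova.tsv", sep="\t", index_label="term")
    _log(log, "ecostats: PERMANOVA trial p = "
              f"{perma.loc['trial', 'p']:.4g}")

    # regression battery on inoculated plots / all plots
    inoc_meta = meta[meta["inoculated"]].merge(
        yr["response"], left_on="sample_id", right_index=True)
    lm_candidates = ["tracked_pct", "p_level", "phosphate_absorption",
                     "nitrate_n", "exchangeable_k"]
    lm = ecostats.stepwise_lm(inoc_meta, "response", lm_candidates)
    glmm_df = meta[meta["inoculated"]].copy()
    glmm_df["tracked_reads"] = (
        track_df.loc[glmm_df["sample_id"], "tracked_reads"].to_numpy())
    glmm = ecostats.logistic_glmm(
        glmm_df, "tracked_reads", config.rarefaction_depth,
        ["mpn", "p_level", "phosphate_absorption", "nitrate_n",
         "exchangeable_k"], group="block")
    fits = {
        "stepwise_lm": {
            "terms": lm.terms,
            "params": {k: float(v) for k, v in lm.params.items()},
            "std_coefs": {k: float(v) for k, v in lm.std_coefs.items()},
            "aic": lm.aic,
        },
        "logistic_glmm": {
            "terms": glmm.terms,
            "params": {k: float(v) for k, v in glmm.params.items()},
            "odds_ratios": {k: float(v) for k, v in glmm.odds_ratios.items()},
            "re_sd": glmm.re_sd,
            "aic": glmm.aic,
        },
    }
    (out / "regressions.json").write_text(json.dumps(fits, indent=2,
                                                     sort_keys=True))
    _log(log, f"regressions: lm terms={lm.terms}; glmm mpn coef="
              f"{glmm.params.get('mpn', float('nan')):.3g}")

    dil_path = ind / "dilution_series.tsv"
    mpn_df = None
    if dil_path.exists():
        dil = pd.read_csv(dil_path, sep="\t")
        mpn_df = mpn.mpn_batch(dil)
        mpn_df.to_csv(out / "mpn.tsv", sep="\t", index=False)
        _log(log, "mpn: " + ", ".join(
            f"{r.trial}={r.mean:.3g}" for r in mpn_df.itertuples()))

    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return {
        "otu_table": table, "rarefied": rarefied, "tracking": track_df,
        "inoculum_set": inoc_set, "yield_response": yr, "commonness": comm,
        "robustness": rob, "permanova": perma, "stepwise_lm": lm,
        "logistic_glmm": glmm, "mpn": mpn_df, "qc": table.qc,
    }
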