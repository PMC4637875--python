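"""End-to-end orchestration: run the three analysis stages from a single
config, write file-based intermediates, and record a run manifest with
input/output checksums so identical configs reproduce identical bytes.

Also provides :func:`make_demo`, which generates a complete synthetic
input bundle mimicking the study design: a small RNA library dominated
(~70%) by the knocked-out miRNA, paired WT/KO expression in which
predicted targets derepress in proportion to site strength, planted
indirect up/down effects, a fixture DE table, and cell-state signatures
planted so the up-set enriches naive/memory-like sets and the down-set
an effector-like set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .derepression import (
    DEFAULT_BIN_EDGES,
    bin_by_strength,
    compute_log2fc,
    derepression_analysis,
    select_background,
    select_targets,
)
from .enrichment import classify_de, enrichment_report, read_gmt
from .quant import (
    composition_table,
    dominant_isoform_counts,
    filter_reads,
    match_to_hairpins,
    parse_fastq,
)
from .simulate import (
    ExprSimConfig,
    ReadSimConfig,
    gen_de_table,
    gen_expression,
    gen_hairpins,
    gen_signatures,
    gen_smallrna_fastq,
    write_fasta,
    write_fastq,
    write_gmt,
)

__all__ = ["RunManifest", "run_pipeline", "make_demo", "read_hairpin_fasta",
           "DEMO_COMPOSITION"]

log = logging.getLogger("mirderep")

KO_MIRNA = "mmu-miR-150"

# ten miRNAs at >= 1% (the knocked-out one at 70%) plus two minor ones,
# mimicking a composition plot of the most abundant miRNAs
DEMO_COMPOSITION = {
    "mmu-miR-150": 0.70, "mmu-miR-16": 0.08, "mmu-miR-21": 0.06,
    "mmu-miR-142": 0.04, "mmu-let-7a": 0.03, "mmu-miR-29a": 0.025,
    "mmu-miR-155": 0.02, "mmu-miR-26a": 0.015, "mmu-miR-101a": 0.012,
    "mmu-miR-103": 0.01, "mmu-miR-191": 0.004, "mmu-miR-25": 0.004,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: list[str] = field(default_factory=list)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    decisions: dict[str, str] = field(default_factory=lambda: {
        "score_boundary": "threshold-inclusive (<=) for targets and background",
        "bin_convention": "[lower, upper) score bins; strongest stratum "
                          "strictly below its edge",
        "isoform_tie_break": "smaller start, then larger end",
        "filter_precedence": "qc_fail > no_adapter > too_short > ambiguous",
    })

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
            "decisions": self.decisions,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_hairpin_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _read_sample_map(path) -> tuple[list[str], list[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "condition"} <= set(df.columns):
        raise ValueError("sample map needs columns: sample, condition")
    wt = df.loc[df["condition"].str.upper() == "WT", "sample"].tolist()
    ko = df.loc[df["condition"].str.upper() == "KO", "sample"].tolist()
    if not wt or not ko:
        raise ValueError("sample map must contain both WT and KO samples")
    return wt, ko


# ---------------------------------------------------------------------------
# stages


def run_quant_stage(cfg: Mapping[str, Any], out_dir: Path) -> dict[str, Path]:
    fastq = Path(cfg["fastq"])
    hairpins = read_hairpin_fasta(cfg["hairpins"])
    adapter = cfg.get("adapter", "TGGAAT")
    min_len = int(cfg.get("min_len", 15))
    max_mm = int(cfg.get("max_mismatches", 0))
    if cfg.get("genome_filter"):
        raise NotImplementedError("--genome-filter is a reserved hook")

    clean, report = filter_reads(parse_fastq(fastq), adapter=adapter, min_len=min_len)
    log.info("quant: filter %s", report.to_dict())
    matches = match_to_hairpins(clean, hairpins, max_mismatches=max_mm)
    profile = dominant_isoform_counts(matches)
    comp = composition_table(profile)

    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "filter_report.json": out_dir / "filter_report.json",
        "filter_report.tsv": out_dir / "filter_report.tsv",
        "mirna_counts.tsv": out_dir / "mirna_counts.tsv",
        "composition.tsv": out_dir / "composition.tsv",
    }
    outputs["filter_report.json"].write_text(
        json.dumps({**report.to_dict(),
                    "n_ambiguous_mapping": profile.n_ambiguous_mapping,
                    "n_unassigned": profile.n_unassigned}, indent=2) + "\n")
    pd.DataFrame([report.to_dict()]).to_csv(outputs["filter_report.tsv"],
                                            sep="\t", index=False)
    profile.to_frame().to_csv(outputs["mirna_counts.tsv"], sep="\t", index=False)
    comp.to_csv(outputs["composition.tsv"], sep="\t", index=False)
    return outputs


def run_derepression_stage(cfg: Mapping[str, Any], out_dir: Path) -> dict[str, Path]:
    expr = pd.read_csv(cfg["expression"], sep="\t", index_col="gene")
    wt, ko = _read_sample_map(cfg["sample_map"])
    scores = pd.read_csv(cfg["scores"], sep="\t")
    mirna = cfg.get("mirna", KO_MIRNA)
    edges = tuple(cfg.get("bin_edges", DEFAULT_BIN_EDGES))
    pseudocount = float(cfg.get("pseudocount", 0.1))
    min_expression = float(cfg.get("min_expression", 1.0))

    lfc = compute_log2fc(expr, wt, ko, pseudocount=pseudocount,
                         min_expression=min_expression)
    # targets selected at the weakest bin edge so the weak bin is populated
    targets = select_targets(scores, mirna, threshold=edges[0])
    background = select_background(scores, mirna, threshold=edges[0])
    bins = bin_by_strength(targets, scores, mirna, edges=edges)
    result = derepression_analysis(lfc, bins, background, scores=scores, mirna=mirna)
    log.info("derepress: %d targets, %d background, monotone=%s",
             sum(b.n for b in result.bins), result.background_n, result.monotone)

    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "derepression.json": out_dir / "derepression.json",
        "cdf_coordinates.tsv": out_dir / "cdf_coordinates.tsv",
        "log2fc.tsv": out_dir / "log2fc.tsv",
    }
    outputs["derepression.json"].write_text(
        json.dumps(result.to_dict(), indent=2) + "\n")
    frames = [b.cdf.assign(set=b.bin.label) for b in result.bins]
    frames.append(result.background_cdf.assign(set="background"))
    pd.concat(frames, ignore_index=True).to_csv(
        outputs["cdf_coordinates.tsv"], sep="\t", index=False)
    lfc.to_frame().to_csv(outputs["log2fc.tsv"], sep="\t")
    return outputs


def run_enrichment_stage(cfg: Mapping[str, Any], out_dir: Path) -> dict[str, Path]:
    de = pd.read_csv(cfg["de"], sep="\t")
    signatures = read_gmt(cfg["signatures"])
    fdr = float(cfg.get("fdr", 0.05))
    up, down, universe = classify_de(de, fdr=fdr)
    log.info("enrich: %d DE genes (%d up, %d down) of %d",
             len(up) + len(down), len(up), len(down), len(universe))
    report = enrichment_report(up, down, signatures, universe)

    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "enrichment.tsv": out_dir / "enrichment.tsv",
        "enrichment.json": out_dir / "enrichment.json",
        "de_classification.json": out_dir / "de_classification.json",
    }
    report.to_csv(outputs["enrichment.tsv"], sep="\t", index=False)
    outputs["enrichment.json"].write_text(
        report.to_json(orient="records", indent=2) + "\n")
    outputs["de_classification.json"].write_text(json.dumps({
        "fdr": fdr, "n_universe": len(universe),
        "n_de": len(up) + len(down), "n_up": len(up), "n_down": len(down),
    }, indent=2) + "\n")
    return outputs


_STAGE_RUNNERS = {
    "quant": run_quant_stage,
    "derepress": run_derepression_stage,
    "enrich": run_enrichment_stage,
}


def run_pipeline(config: Mapping[str, Any], out_dir) -> RunManifest:
    """Execute the enabled stages in order (quant -> derepress ->
    enrich); each stage reads file inputs named in its config section
    and writes TSV/JSON artifacts under ``out_dir/<stage>/``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["quant", "derepress", "enrich"])
    unknown = [s for s in stages if s not in _STAGE_RUNNERS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")

    manifest = RunManifest(version=__version__, config=dict(config),
                           started=time.time())
    for stage in stages:
        section = config.get(stage)
        if section is None:
            raise ValueError(f"stage {stage!r} enabled but not configured")
        for key, value in section.items():
            p = Path(str(value))
            if key in ("fastq", "hairpins", "expression", "sample_map",
                       "scores", "de", "signatures"):
                if not p.exists():
                    raise FileNotFoundError(f"stage {stage!r}: missing input {p}")
                manifest.inputs[f"{stage}/{key}"] = _sha256(p)
        try:
            outputs = _STAGE_RUNNERS[stage](section, out_dir / stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages.append(stage)
        for name, path in outputs.items():
            manifest.outputs[f"{stage}/{name}"] = _sha256(path)
    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# demo bundle


def make_demo(seed: int, out_dir, n_reads: int = 20_000,
              n_genes: int = 10_000) -> dict[str, Path]:
    """Generate the full synthetic input bundle plus a ready-to-run
    pipeline config. All randomness derives from the single seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    hairpins = gen_hairpins(len(DEMO_COMPOSITION), length=72, seed=int(sub[0]),
                            names=list(DEMO_COMPOSITION))
    read_cfg = ReadSimConfig(
        n_reads=n_reads, composition=DEMO_COMPOSITION,
        n_qc_fail=n_reads // 100, n_no_adapter=n_reads // 150,
        n_short_insert=n_reads // 125, n_ambiguous=n_reads // 250,
        seed=int(sub[1]),
    )
    reads, read_truth = gen_smallrna_fastq(read_cfg, hairpins)

    expr_cfg = ExprSimConfig(
        n_genes=n_genes, n_replicates_per_arm=6, beta=1.0, noise_sd=0.25,
        n_indirect_up=max(1, n_genes // 25), n_indirect_down=max(1, n_genes // 20),
        indirect_lfc=0.8, seed=int(sub[2]),
    )
    sim = gen_expression(expr_cfg)
    de = gen_de_table(sim.expr, sim.wt_samples, sim.ko_samples)
    up, down, universe = classify_de(de)
    signatures = gen_signatures(
        sorted(universe),
        designated={"naive": sorted(up), "memory": sorted(up),
                    "effector": sorted(down)},
        sizes=200, planted_enrichment=3.0, seed=int(sub[3]),
    )

    paths = {
        "hairpins": out / "hairpins.fasta",
        "fastq": out / "reads.fastq",
        "expression": out / "expression.tsv",
        "sample_map": out / "sample_map.tsv",
        "scores": out / "target_scores.tsv",
        "de": out / "de_table.tsv",
        "signatures": out / "signatures.gmt",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }
    write_fasta(hairpins, paths["hairpins"])
    write_fastq(reads, paths["fastq"])
    sim.expr.to_csv(paths["expression"], sep="\t")
    pd.DataFrame({
        "sample": sim.wt_samples + sim.ko_samples,
        "condition": ["WT"] * len(sim.wt_samples) + ["KO"] * len(sim.ko_samples),
    }).to_csv(paths["sample_map"], sep="\t", index=False)
    sim.scores.to_csv(paths["scores"], sep="\t", index=False)
    de.to_csv(paths["de"], sep="\t", index=False)
    write_gmt(signatures, paths["signatures"])
    paths["truth"].write_text(json.dumps({
        "seed": seed,
        "read_truth": {
            "n_clean": read_truth.n_clean,
            "clean_counts": read_truth.clean_counts,
            "dominant_counts": read_truth.dominant_counts,
            "planted_failures": {
                "qc_fail": read_truth.n_qc_fail,
                "no_adapter": read_truth.n_no_adapter,
                "short_insert": read_truth.n_short_insert,
                "ambiguous": read_truth.n_ambiguous,
            },
        },
        "expression_truth": {
            "beta": expr_cfg.beta,
            "n_targets": int(sim.truth["is_target"].sum()),
            "n_indirect_up": expr_cfg.n_indirect_up,
            "n_indirect_down": expr_cfg.n_indirect_down,
        },
    }, indent=2) + "\n")

    config = {
        "seed": seed,
        "stages": ["quant", "derepress", "enrich"],
        "quant": {"fastq": str(paths["fastq"]), "hairpins": str(paths["hairpins"]),
                  "adapter": "TGGAAT", "min_len": 15},
        "derepress": {"expression": str(paths["expression"]),
                      "sample_map": str(paths["sample_map"]),
                      "scores": str(paths["scores"]), "mirna": KO_MIRNA,
                      "bin_edges": list(DEFAULT_BIN_EDGES)},
        "enrich": {"de": str(paths["de"]), "signatures": str(paths["signatures"]),
                   "fdr": 0.05},
    }
    import yaml

    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths
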