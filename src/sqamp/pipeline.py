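"""End-to-end orchestration: resources -> verify -> place -> otu ->
diversity -> taxonomy -> enrich, from a single validated configuration.

Outputs are deterministic given the seeds in the config.  Each run writes
per-stage tables, a jplace file, two figure-style summaries (per-sample
verified/excluded proportions of reads and ASVs; clade x taxon composition
of placed ASVs) and a JSON manifest with a config hash and per-stage record
counts, so reruns can be verified hash-for-hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .align import AlignerConfig
from .diversity import CountMatrix, rarefaction_profile, rarefaction_summary
from .enrich import nb_wald_test
from .models import ModelConfig
from .otu import cluster_greedy, membership_table, otu_count_table
from .place import OptimizerConfig, place_peptides, write_jplace
from .resources import load_reference, write_reference
from .synth import SynthConfig, simulate_dataset
from .taxonomy import TaxDbEntry, classify_all, clade_composition, load_tax_db
from .verify import Asv, VerifyConfig, verify_asvs

logger = logging.getLogger(__name__)


@dataclass
class InputPaths:
    protein_fasta: Optional[str] = None
    alignment_fasta: Optional[str] = None
    tree_newick: Optional[str] = None
    metadata_tsv: Optional[str] = None
    nt_fasta: Optional[str] = None
    asv_fasta: Optional[str] = None
    counts_tsv: Optional[str] = None
    condition_tsv: Optional[str] = None
    tax_protein_fasta: Optional[str] = None
    tax_taxonomy_tsv: Optional[str] = None


@dataclass
class StageParams:
    verify: VerifyConfig = field(default_factory=VerifyConfig)
    model: str = "LG"
    otu_threshold: float = 0.9
    depths: tuple[int, ...] = (100, 1000, 10000)
    reps: int = 10
    tax_floor: float = 0.9
    tax_rank: str = "class"
    alpha: float = 0.01
    treated: str = "treated"
    control: str = "control"


@dataclass
class PipelineConfig:
    output_dir: str = "sqamp_out"
    seed: int = 42
    synth: Optional[SynthConfig] = None
    inputs: InputPaths = field(default_factory=InputPaths)
    params: StageParams = field(default_factory=StageParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc, data, where):
            names = {f.name for f in dataclasses.fields(dc)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
            return data

        data = dict(build(cls, raw, "top level"))
        if "synth" in data and data["synth"] is not None:
            data["synth"] = SynthConfig(**build(SynthConfig, data["synth"], "synth"))
        if "inputs" in data and data["inputs"] is not None:
            data["inputs"] = InputPaths(**build(InputPaths, data["inputs"], "inputs"))
        if "params" in data and data["params"] is not None:
            p = dict(build(StageParams, data["params"], "params"))
            if "verify" in p and p["verify"] is not None:
                p["verify"] = VerifyConfig(**build(VerifyConfig, p["verify"], "params.verify"))
            if "depths" in p:
                p["depths"] = tuple(p["depths"])
            data["params"] = StageParams(**p)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded
        so reruns into different directories compare equal)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def read_asvs(asv_fasta, counts_tsv) -> list[Asv]:
    """ASV FASTA plus feature-by-sample count TSV."""
    from .resources import _read_fasta

    seqs = _read_fasta(asv_fasta)
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    missing = sorted(set(seqs) - set(counts.index))
    if missing:
        raise ValueError(f"ASVs without counts: {missing}")
    return [Asv(id=i, nt_seq=s,
                counts={c: int(counts.at[i, c]) for c in counts.columns})
            for i, s in seqs.items()]


def write_asvs(asvs: list[Asv], fasta_path, counts_path) -> None:
    with open(fasta_path, "w") as fh:
        for a in asvs:
            fh.write(f">{a.id}\n{a.nt_seq}\n")
    samples = sorted({s for a in asvs for s in a.counts})
    df = pd.DataFrame([{**{"": a.id}, **{s: a.counts.get(s, 0) for s in samples}}
                       for a in asvs]).set_index("")
    df.to_csv(counts_path, sep="\t")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "sqamp", "version": __version__,
                      "config_hash": config.config_hash(), "stages": {}}
    p = config.params

    # --- stage: resources ---------------------------------------------------
    try:
        if config.synth is not None:
            ds = simulate_dataset(config.synth)
            resource, asvs = ds.resource, ds.asvs
            condition = ds.counts.condition
            indir = out / "inputs"
            write_reference(resource, indir)
            write_asvs(asvs, indir / "asvs.fasta", indir / "asv_counts.tsv")
            ds.counts.to_tsv(indir / "asv_counts.tsv", indir / "conditions.tsv")
            ds.truth.asvs.to_csv(indir / "truth_asvs.tsv", sep="\t", index=False)
            tax_db = [TaxDbEntry(id=e.id, protein_seq=e.protein_seq,
                                 taxonomy=e.taxonomy) for e in resource.entries]
        else:
            i = config.inputs
            for name in ("protein_fasta", "alignment_fasta", "tree_newick",
                         "metadata_tsv", "asv_fasta", "counts_tsv"):
                if getattr(i, name) is None:
                    raise ValueError(f"inputs.{name} is required without synth")
            resource = load_reference(i.protein_fasta, i.alignment_fasta,
                                      i.tree_newick, i.metadata_tsv,
                                      nt_fasta=i.nt_fasta)
            asvs = read_asvs(i.asv_fasta, i.counts_tsv)
            condition = {}
            if i.condition_tsv:
                df = pd.read_csv(i.condition_tsv, sep="\t", dtype=str)
                condition = dict(zip(df["sample"], df["condition"]))
            tax_db = (load_tax_db(i.tax_protein_fasta, i.tax_taxonomy_tsv)
                      if i.tax_protein_fasta else
                      [TaxDbEntry(id=e.id, protein_seq=e.protein_seq,
                                  taxonomy=e.taxonomy) for e in resource.entries])
    except Exception as exc:
        raise PipelineError("resources", str(exc)) from exc
    manifest["stages"]["resources"] = {"n_entries": len(resource.entries),
                                       "n_asvs": len(asvs)}
    logger.info("resources: %d reference entries, %d ASVs",
                len(resource.entries), len(asvs))

    # --- stage: verify --------------------------------------------------------
    records = verify_asvs(asvs, resource, p.verify)
    verdicts = pd.DataFrame([{
        "asv_id": r.asv.id, "status": r.verdict.status,
        "reason": r.verdict.reason, "strand": r.translation.strand,
        "frame": r.translation.frame,
        "best_ref": r.verdict.best_hit[0] if r.verdict.best_hit else "",
        "identity": r.verdict.best_hit[1] if r.verdict.best_hit else float("nan"),
        "norm_score": r.verdict.best_hit[2] if r.verdict.best_hit else float("nan"),
    } for r in records])
    verdicts.to_csv(out / "verify_verdicts.tsv", sep="\t", index=False)
    candidates = {r.asv.id: r.translation.peptide for r in records
                  if r.verdict.status == "candidate"}
    manifest["stages"]["verify"] = {
        "n_candidates": len(candidates),
        "n_excluded": len(records) - len(candidates)}

    # --- stage: place --------------------------------------------------------
    placements, unplaceable = place_peptides(
        candidates, resource, ModelConfig(p.model), OptimizerConfig(),
        p.verify.aligner)
    mult = {a.id: a.total_count for a in asvs}
    if placements:
        write_jplace(placements, resource, out / "placements.jplace", mult)
    place_df = pd.DataFrame([{
        "asv_id": pl.asv_id, "edge": pl.best_edge,
        "log_likelihood": pl.log_likelihood,
        "lwr_best": pl.lwr[pl.best_edge],
        "pendant_length": pl.pendant_length,
        "clade_id": pl.clade_id, "verified": pl.verified,
    } for pl in placements])
    place_df.to_csv(out / "placements.tsv", sep="\t", index=False)
    verified_ids = {pl.asv_id for pl in placements if pl.verified}
    manifest["stages"]["place"] = {"n_placed": len(placements),
                                   "n_unplaceable": len(unplaceable),
                                   "n_verified": len(verified_ids)}

    # --- summary: verified/excluded proportions (per sample) ----------------
    samples = sorted({s for a in asvs for s in a.counts})
    summary_rows = []
    for s in samples:
        tot_reads = sum(a.counts.get(s, 0) for a in asvs)
        ver_reads = sum(a.counts.get(s, 0) for a in asvs if a.id in verified_ids)
        present = [a for a in asvs if a.counts.get(s, 0) > 0]
        ver_asvs = [a for a in present if a.id in verified_ids]
        summary_rows.append({
            "sample": s, "reads_total": tot_reads, "reads_verified": ver_reads,
            "pct_reads_verified": 100.0 * ver_reads / tot_reads if tot_reads else 0.0,
            "asvs_total": len(present), "asvs_verified": len(ver_asvs),
            "pct_asvs_verified": (100.0 * len(ver_asvs) / len(present)
                                  if present else 0.0)})
    pd.DataFrame(summary_rows).to_csv(out / "summary_verified.tsv",
                                      sep="\t", index=False)
    # count conservation: every input read is either verified or itemized
    assert sum(r["reads_total"] for r in summary_rows) == \
        sum(a.total_count for a in asvs)

    # --- stage: otu ----------------------------------------------------------
    verified_asvs = [a for a in asvs if a.id in verified_ids]
    clusters = cluster_greedy(verified_asvs, p.otu_threshold)
    if clusters:
        membership_table(clusters).to_csv(out / "otu_membership.tsv",
                                          sep="\t", index=False)
        otu_counts = otu_count_table(clusters, verified_asvs)
        otu_counts.to_csv(out / "otu_counts.tsv", sep="\t")
    manifest["stages"]["otu"] = {"n_otus": len(clusters)}

    # --- stage: diversity ----------------------------------------------------
    ver_counts = pd.DataFrame(
        {s: [a.counts.get(s, 0) for a in verified_asvs] for s in samples},
        index=[a.id for a in verified_asvs])
    div_results = {}
    if not ver_counts.empty:
        cm = CountMatrix(counts=ver_counts, condition=condition)
        prof = rarefaction_profile(cm, p.depths, p.reps, config.seed)
        prof.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
        if not prof.empty:
            rarefaction_summary(prof).to_csv(out / "alpha_summary.tsv",
                                             sep="\t", index=False)
        div_results = {"n_rows": int(len(prof))}
    manifest["stages"]["diversity"] = div_results

    # --- stage: taxonomy -----------------------------------------------------
    ver_peptides = {r.asv.id: r.translation.peptide.replace("*", "X")
                    for r in records if r.asv.id in verified_ids}
    assignments = classify_all(ver_peptides, tax_db, p.tax_floor,
                               p.verify.aligner)
    tax_df = pd.DataFrame([{
        "asv_id": a.asv_id, "hit_id": a.hit_id or "",
        "identity": a.identity if a.identity is not None else float("nan"),
        "taxonomy": ";".join(a.ranks)} for a in assignments])
    tax_df.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    ver_placements = [pl for pl in placements if pl.asv_id in ver_peptides]
    if ver_placements:
        comp = clade_composition(ver_placements, assignments, p.tax_rank)
        comp.to_csv(out / "clade_composition.tsv", sep="\t", index=False)
    manifest["stages"]["taxonomy"] = {
        "n_classified": sum(a.classified for a in assignments),
        "n_unclassified": sum(not a.classified for a in assignments)}

    # --- stage: enrich -------------------------------------------------------
    if condition and len(set(condition.values())) == 2:
        all_counts = pd.DataFrame(
            {s: [a.counts.get(s, 0) for a in asvs] for s in samples},
            index=[a.id for a in asvs])
        cm = CountMatrix(counts=all_counts, condition=condition)
        res = nb_wald_test(cm, p.treated, p.control, p.alpha)
        res.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "n_significant": int(res.significant.sum())}
    else:
        logger.info("enrich: skipped (need exactly two conditions)")
        manifest["stages"]["enrich"] = {"skipped": True}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out
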