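"""End-to-end orchestration of the DNA-authentication workflow on simulated
or user-supplied inputs, with a provenance manifest.

Stages run in dependency order: simulate (optional) -> qc -> screen ->
assign -> damage. Every stage boundary is reconciled in the manifest
(reads in = reads removed + reads passed) and all file outputs are
checksummed so a rerun with the same config and seed is verifiable as
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assign as assign_mod
from . import damage as damage_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from . import taxscreen
from .core import write_fastq, write_sam

logger = logging.getLogger("sedsift")

DEFAULTS = {
    "qc": {"min_len": 30, "min_mean_q": 20.0, "dust_threshold": 7.0, "dedup": True},
    "screen": {"min_escore": 7.0, "min_reads": 10, "min_rel_abundance": 0.0002,
               "min_genus_mito_hits": 4},
    "assign": {"min_mapq": 30},
    "damage": {"n_positions": 30, "terminal_k": [3, 5], "min_reads_gate": 100},
    "simulate": {"n_reads": 10000, "error_rate": 0.001,
                 "contamination_fraction": 0.0, "delta5": 0.2, "decay": 0.6,
                 "delta_base": 0.01},
}

_KNOWN_KEYS = set(DEFAULTS) | {"seed", "out_dir"}


def validate_config(config: dict) -> dict:
    """Merge user config over the field-standard default parameters; reject unknown keys
    before any stage runs."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    merged = {"seed": config.get("seed", 0), "out_dir": config.get("out_dir", ".")}
    for stage, defaults in DEFAULTS.items():
        block = dict(defaults)
        user = config.get(stage, {})
        bad = set(user) - set(defaults)
        if bad:
            raise ValueError(f"unknown key(s) in [{stage}]: {', '.join(sorted(bad))}")
        block.update(user)
        merged[stage] = block
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def record_stage(self, name: str, **counts) -> None:
        self.stages[name] = {**counts, "timestamp": time.time()}

    def record_file(self, path: Path) -> None:
        self.files[path.name] = _sha256(path)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "stages": self.stages,
                 "files": self.files},
                fh,
                indent=2,
            )


def _default_mixture(seed: int) -> tuple[list[sim_mod.TaxonSpec], dict[str, int]]:
    """Three-taxon study mixture with mitochondrial references."""
    import numpy as np

    rng = np.random.default_rng(seed)
    specs = []
    layout = [
        ("ovis", "Ovis aries", "Ovis", 0.5),
        ("canis", "Canis lupus", "Canis", 0.3),
        ("rattus", "Rattus rattus", "Rattus", 0.2),
    ]
    lengths = {}
    for taxon_id, name, genus, ab in layout:
        seq = "".join(rng.choice(list("ACGT"), size=16000))
        specs.append(
            sim_mod.TaxonSpec(
                taxon_id=taxon_id,
                name=name,
                genus=genus,
                abundance=ab,
                references=[sim_mod.ReferenceSeq(f"{taxon_id}_mt", "mitochondrion", seq)],
            )
        )
        lengths[f"{taxon_id}_mt"] = len(seq)
    return specs, lengths


def run_pipeline(config: dict) -> RunManifest:
    """Execute simulate -> qc -> screen -> assign -> damage and write all
    stage outputs plus a manifest under ``out_dir``."""
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
    )

    # --- simulate ---------------------------------------------------------
    sim_cfg = cfg["simulate"]
    mixture, genome_lengths = _default_mixture(cfg["seed"])
    dmg = sim_mod.DamageModel(
        delta5=sim_cfg["delta5"], decay=sim_cfg["decay"], delta_base=sim_cfg["delta_base"]
    )
    reads, truth, alignments = sim_mod.simulate_metagenome(
        mixture,
        sim_mod.FragmentModel(),
        dmg,
        sim_mod.SimConfig(
            seed=cfg["seed"],
            n_reads=sim_cfg["n_reads"],
            error_rate=sim_cfg["error_rate"],
            contamination_fraction=sim_cfg["contamination_fraction"],
        ),
    )
    fastq = out_dir / "reads.fastq"
    write_fastq(reads, fastq)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    sam = out_dir / "alignments.sam"
    write_sam(alignments, genome_lengths, sam)
    manifest.record_stage("simulate", n_reads=len(reads), n_truth=len(truth))
    for p in (fastq, out_dir / "truth.tsv", sam):
        manifest.record_file(p)
    logger.info("simulate: %d reads", len(reads))

    # --- qc ---------------------------------------------------------------
    params = qc_mod.QCParams(**cfg["qc"])
    kept, report = qc_mod.qc_filter(reads, params)
    write_fastq(kept, out_dir / "reads.qc.fastq")
    if not report.reconciles():
        raise RuntimeError("qc report does not reconcile")
    manifest.record_stage("qc", **report.as_dict())
    manifest.record_file(out_dir / "reads.qc.fastq")
    logger.info("qc: kept %d / %d", report.n_kept, report.n_input)

    # --- screen -----------------------------------------------------------
    kept_ids = {r.read_id for r in kept}
    truth_kept = truth[truth["read_id"].isin(kept_ids)]
    report_df = sim_mod.synth_tax_report(truth_kept, mixture)
    taxscreen.write_report(report_df, out_dir / "taxreport.tsv")
    parsed = taxscreen.parse_report(out_dir / "taxreport.tsv")
    species = taxscreen.add_escore(parsed[parsed["rank"] == "species"].copy())
    genus_of = {t.name: t.genus for t in mixture}
    species["genus"] = species["name"].map(genus_of)
    scr = cfg["screen"]
    candidates = taxscreen.select_candidates(
        species,
        min_genus_mito_hits=scr["min_genus_mito_hits"],
        min_escore=scr["min_escore"],
    )
    candidates.candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    manifest.record_stage(
        "screen",
        n_species=len(species),
        n_candidates=len(candidates.candidates),
        n_unplaced=len(candidates.unplaced),
    )
    manifest.record_file(out_dir / "candidates.tsv")

    # --- assign -----------------------------------------------------------
    aln_kept = [a for a in alignments if a.read_id in kept_ids]
    result = assign_mod.assign_reads(
        aln_kept, min_mapq=cfg["assign"]["min_mapq"], all_read_ids=sorted(kept_ids)
    )
    result.to_frame().to_csv(out_dir / "assignments.tsv", sep="\t", index=False)
    if result.n_total != len(kept_ids):
        raise RuntimeError("assignment does not partition the read set")
    manifest.record_stage(
        "assign",
        n_assigned=len(result.assigned),
        **{f"n_{k}": v for k, v in result.reason_counts().items()},
    )
    manifest.record_file(out_dir / "assignments.tsv")

    # --- damage -----------------------------------------------------------
    dmg_cfg = cfg["damage"]
    per_ref_damage: dict[str, float] = {}
    profile_frames = []
    by_ref: dict[str, list] = {}
    for aln in aln_kept:
        if aln.read_id in result.assigned and result.assigned[aln.read_id] == aln.ref_id:
            by_ref.setdefault(aln.ref_id, []).append(aln)
    for ref_id, alns in by_ref.items():
        profile = damage_mod.misincorporation_profile(
            alns, n_positions=dmg_cfg["n_positions"]
        )
        summary = damage_mod.terminal_damage(
            profile, k=dmg_cfg["terminal_k"][0], min_reads=dmg_cfg["min_reads_gate"]
        )
        if summary.gate_passed and summary.value is not None:
            per_ref_damage[ref_id] = summary.value
        frame = profile.to_frame()
        frame.insert(0, "ref_id", ref_id)
        profile_frames.append(frame)
    if profile_frames:
        pd.concat(profile_frames).to_csv(
            out_dir / "misincorporation.tsv", sep="\t", index=False
        )
        manifest.record_file(out_dir / "misincorporation.tsv")

    stats = assign_mod.taxon_stats(result, aln_kept, genome_lengths, per_ref_damage)
    pd.DataFrame([s.as_dict() for s in stats]).to_csv(
        out_dir / "taxon_stats.tsv", sep="\t", index=False
    )
    manifest.record_stage("damage", n_references=len(by_ref))
    manifest.record_file(out_dir / "taxon_stats.tsv")

    manifest.write(out_dir / "manifest.json")
    return manifest
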