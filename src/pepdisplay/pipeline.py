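"""Reproducible end-to-end runs: config, orchestration, fixtures.

A run config (YAML or dict) names the library design, the sample
manifest (each sorted sample explicitly matched to one unsorted
sample), and the scoring options. ``run_pipeline`` executes
process -> count -> score for every matched pair and writes all tables
plus a manifest with content digests, so identical inputs and config
give byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .counting import count_peptides, position_residue_counts, scanning_matrix_counts
from .design import LibraryDesign
from .reads import ProcessingParams, process_sample, write_peptide_table
from .scoring import (
    amber_position_enrichment,
    enrichment_scores,
    position_enrichment,
    scanning_enrichment,
    select_for_logo,
)
from .simulate import SimulationConfig, SpecificityModel, simulate_screen

logger = logging.getLogger("pepdisplay")


@dataclass
class SampleSpec:
    sample_id: str
    role: str  # "sorted" | "unsorted"
    r1: str
    r2: Optional[str] = None
    matched_unsorted: Optional[str] = None
    replicate_group: str = ""


@dataclass
class RunConfig:
    design: LibraryDesign
    samples: list
    pseudocount: float = 0.0
    log_base: int = 2
    filter_mode: str = "full"
    logo_cutoff: float = 3.0
    amber_analysis: bool = False
    figures: bool = False
    seed: int = 0
    processing: ProcessingParams = field(default_factory=ProcessingParams)

    def validate(self) -> None:
        ids = {s.sample_id for s in self.samples}
        if len(ids) != len(self.samples):
            raise ValueError("duplicate sample ids")
        for s in self.samples:
            if s.role not in ("sorted", "unsorted"):
                raise ValueError(f"sample {s.sample_id}: unknown role {s.role!r}")
            if s.role == "sorted":
                if not s.matched_unsorted:
                    raise ValueError(f"sorted sample {s.sample_id} has no matched unsorted sample")
                match = [x for x in self.samples if x.sample_id == s.matched_unsorted]
                if len(match) != 1 or match[0].role != "unsorted":
                    raise ValueError(
                        f"sorted sample {s.sample_id} must name exactly one unsorted sample"
                    )
            for p in (s.r1, s.r2):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"sample {s.sample_id}: missing input {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        base = Path(path).parent
        design = d["design"]
        if isinstance(design, str):
            with open(base / design) as fh:
                design = yaml.safe_load(fh)
        samples = []
        for s in d["samples"]:
            s = dict(s)
            for key in ("r1", "r2"):
                if s.get(key):
                    s[key] = str(base / s[key]) if not Path(s[key]).is_absolute() else s[key]
            samples.append(SampleSpec(**s))
        scoring = d.get("scoring", {})
        return cls(
            design=LibraryDesign.from_dict(design),
            samples=samples,
            pseudocount=float(scoring.get("pseudocount", 0.0)),
            log_base=int(scoring.get("log_base", 2)),
            filter_mode=scoring.get("filter_mode", "full"),
            logo_cutoff=float(scoring.get("logo_cutoff", 3.0)),
            amber_analysis=bool(scoring.get("amber_analysis", False)),
            figures=bool(d.get("figures", False)),
            seed=int(d.get("seed", 0)),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute process -> count -> score for every matched pair.

    Writes per-sample peptide tables and QC JSON, per-pair enrichment
    outputs appropriate to the design kind, and ``manifest.json`` with
    a digest of every output file. Returns the manifest dict.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = config.design
    outputs: list = []

    records: dict = {}
    for s in config.samples:
        logger.info("processing sample %s (%s)", s.sample_id, s.role)
        recs, stats = process_sample(s.r1, s.r2, design, config.processing, s.sample_id)
        records[s.sample_id] = recs
        pep_path = out_dir / f"{s.sample_id}.peptides.tsv"
        write_peptide_table(recs, pep_path)
        qc_path = out_dir / f"{s.sample_id}.qc.json"
        stats.to_json(qc_path)
        outputs += [pep_path, qc_path]
        logger.info("sample %s: %d/%d reads ok", s.sample_id, stats.reads_ok, stats.reads_in)

    labels = design.position_labels()
    whitelist = set(design.members) if design.kind == "defined" else None
    for s in config.samples:
        if s.role != "sorted":
            continue
        pair_id = f"{s.sample_id}_vs_{s.matched_unsorted}"
        recs_s = records[s.sample_id]
        recs_u = records[s.matched_unsorted]
        ct_s = count_peptides(recs_s, whitelist, s.sample_id, sorted_flag=True)
        ct_u = count_peptides(recs_u, whitelist, s.matched_unsorted, sorted_flag=False)
        for ct in (ct_s, ct_u):
            p = out_dir / f"{ct.sample_id}.counts.tsv"
            ct.to_tsv(p)
            outputs.append(p)
        if design.kind == "defined":
            table = enrichment_scores(ct_s, ct_u, config.pseudocount)
            p = out_dir / f"{pair_id}.enrichment.tsv"
            table.to_csv(p, sep="\t")
            outputs.append(p)
            fg, bg, fg_freq, bg_freq = select_for_logo(table, config.logo_cutoff)
            for name, df in (("foreground", fg_freq), ("background", bg_freq)):
                p = out_dir / f"{pair_id}.logo_{name}.tsv"
                df.to_csv(p, sep="\t")
                outputs.append(p)
        elif design.kind == "degenerate":
            ms = position_residue_counts(recs_s, design.peptide_length, config.filter_mode, labels, s.sample_id)
            mu = position_residue_counts(recs_u, design.peptide_length, config.filter_mode, labels, s.matched_unsorted)
            for m in (ms, mu):
                p = out_dir / f"{m.sample_id}.position_counts.tsv"
                m.to_tsv(p)
                outputs.append(p)
            pe = position_enrichment(ms, mu, design.masked_positions(), config.pseudocount)
            which = "log2" if config.log_base == 2 else "log10"
            p = out_dir / f"{pair_id}.position_enrichment.tsv"
            pe.to_tsv(p, which)
            outputs.append(p)
            if config.amber_analysis:
                ape = amber_position_enrichment(recs_s, recs_u, design, config.pseudocount)
                p = out_dir / f"{pair_id}.amber_position_enrichment.tsv"
                ape.to_tsv(p, which)
                outputs.append(p)
            if config.figures:
                from .scoring import plot_heatmap

                p = out_dir / f"{pair_id}.position_enrichment.png"
                plot_heatmap(getattr(pe, which), p, title=pair_id)
                outputs.append(p)
        else:  # scanning
            sm_s = scanning_matrix_counts(ct_s, design.reference_peptide, labels)
            sm_u = scanning_matrix_counts(ct_u, design.reference_peptide, labels)
            se = scanning_enrichment(sm_s, sm_u, log_base=10 if config.log_base == 10 else config.log_base, pseudocount=config.pseudocount)
            p = out_dir / f"{pair_id}.scanning_enrichment.tsv"
            se.log_normalized.to_csv(p, sep="\t")
            outputs.append(p)
            if config.figures:
                from .scoring import plot_heatmap

                p = out_dir / f"{pair_id}.scanning_enrichment.png"
                plot_heatmap(se.log_normalized, p, title=pair_id)
                outputs.append(p)

    manifest = {
        "pepdisplay_version": __version__,
        "seed": config.seed,
        "design": design.to_dict(),
        "scoring": {
            "pseudocount": config.pseudocount,
            "log_base": config.log_base,
            "filter_mode": config.filter_mode,
            "logo_cutoff": config.logo_cutoff,
            "amber_analysis": config.amber_analysis,
        },
        "inputs": {
            s.sample_id: {
                "r1": _sha256(s.r1),
                "r2": _sha256(s.r2) if s.r2 else None,
                "role": s.role,
                "matched_unsorted": s.matched_unsorted,
            }
            for s in config.samples
        },
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


FIXTURE_SCENARIOS = ("defined-10", "degenerate-small", "scanning-11mer", "amber")

_DEFINED_10 = (
    "EPQYEEIPIYL",  # Src-optimal-like, one Tyr... (contains 2 Y) kept for variety
    "EDAIYAAPFAK",
    "AEEEIYGEFEA",
    "GGQDIYETDYY",
    "LDNLIYAATNL",
    "KKGHEYTNIKY",
    "PVPEIPAAPSS",  # no Tyr: internal negative control
    "RRLIEDAEYAA",
    "TEGQYQPQPAS",
    "NEYTARQGAKF",
)


def make_fixtures(scenario: str, seed: int, out_dir) -> dict:
    """Generate a desk-scale synthetic screen (design + model + FASTQ +
    truth) for a documented scenario."""
    if scenario not in FIXTURE_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {FIXTURE_SCENARIOS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if scenario == "defined-10":
        design = LibraryDesign(kind="defined", peptide_length=11, members=_DEFINED_10)
        model = SpecificityModel.from_preferences(
            11, {(3, "I"): 1.0, (7, "E"): 0.8, (5, "Y"): 0.5},
            baseline_rate=0.2,
        )
        config = SimulationConfig(design=design, n_cells=20_000, reads_per_sample=20_000, seed=seed)
    elif scenario == "degenerate-small":
        design = LibraryDesign.x5_y_x5()
        labels = design.position_labels()
        model = SpecificityModel.from_preferences(
            11,
            {(-2, "I"): 1.2, (-1, "E"): 0.8, (1, "E"): 0.9, (3, "F"): 0.7, (-3, "D"): 0.5},
            positions=labels,
            baseline_rate=0.2,
        )
        config = SimulationConfig(design=design, n_cells=50_000, reads_per_sample=50_000, seed=seed)
    elif scenario == "scanning-11mer":
        design = LibraryDesign.src_consensus_scanning()
        model = SpecificityModel.from_preferences(
            11,
            {(4, "I"): 0.8, (6, "D"): 0.6, (5, "Y"): 2.0, (5, "*"): -3.0,
             (3, "P"): -0.7},
            baseline_rate=0.05,
        )
        config = SimulationConfig(design=design, n_cells=50_000, reads_per_sample=50_000, seed=seed)
    else:  # amber
        design = LibraryDesign.x5_y_x5()
        labels = design.position_labels()
        import math

        model = SpecificityModel.from_preferences(
            11, {(1, "*"): math.log(3.0), (-2, "I"): 0.8},
            positions=labels,
            baseline_rate=0.2,
        )
        config = SimulationConfig(design=design, n_cells=60_000, reads_per_sample=60_000, seed=seed)

    result = simulate_screen(config, model, out_dir)
    with open(out_dir / "design.yaml", "w") as fh:
        yaml.safe_dump(design.to_dict(), fh)
    model.to_json(out_dir / "model.json")
    run_cfg = {
        "design": "design.yaml",
        "seed": seed,
        "scoring": {"amber_analysis": scenario == "amber",
                    "filter_mode": "nostop" if scenario == "amber" else "full"},
        "samples": [
            {
                "sample_id": "sorted_1",
                "role": "sorted",
                "r1": result["sorted_files"]["r1"].name,
                "r2": result["sorted_files"]["r2"].name,
                "matched_unsorted": "unsorted_1",
            },
            {
                "sample_id": "unsorted_1",
                "role": "unsorted",
                "r1": result["unsorted_files"]["r1"].name,
                "r2": result["unsorted_files"]["r2"].name,
            },
        ],
    }
    with open(out_dir / "run.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh)
    result["run_config"] = out_dir / "run.yaml"
    result["design"] = design
    result["model"] = model
    return result
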