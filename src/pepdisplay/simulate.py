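"""Synthetic display-screen generator with known ground truth.

The simulator emulates the full experiment: a finite cell population
sampled from a library design, kinase phosphorylation of displayed
peptides under a position-weight specificity model with first-order
kinetics, antibody/bead capture of phosphorylated cells, and paired-end
amplicon sequencing with the real flank architecture (randomized 6-N
stretches, constant anchors, NNS-consistent coding sequence).

The phosphorylation model: each peptide's reaction extent after
exposure ``t`` is ``p = 1 - exp(-k0 * t * exp(sum of position
weights))`` — a first-order reaction whose rate is modulated
multiplicatively by the residues surrounding the phospho-acceptor.
``calibrate_exposure`` finds the exposure at which the population-mean
extent hits a target (the protocol aims for 25-50% phosphorylation
before selection).

Capture is Bernoulli per cell: ``capture_efficiency`` for
phosphorylated cells, ``background_capture`` otherwise. These defaults
(0.9 / 0.01) are simulation parameters, not biological estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .design import (
    AMBER,
    DEFAULT_CODON_TABLE,
    DOWNSTREAM_CONST,
    LibraryDesign,
    ROW_ORDER,
    UPSTREAM_CONST,
    nns_codons,
    translate_codon,
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _nns_by_residue() -> dict:
    by_res: dict = {}
    for codon in nns_codons():
        aa = translate_codon(codon)
        by_res.setdefault(aa, []).append(codon.lower())
    return by_res


_NNS_BY_RESIDUE = _nns_by_residue()
_NNS_CODON_LIST = [c.lower() for c in nns_codons()]
_NNS_AA = [translate_codon(c) for c in _NNS_CODON_LIST]


@dataclass
class SpecificityModel:
    """Ground-truth position weights plus first-order kinetics.

    ``weights`` is a (residue x position) DataFrame of log-preferences
    (0 = neutral); rows cover the 20 canonical residues plus ``*`` for
    the amber-encoded non-canonical residue.
    """

    weights: pd.DataFrame
    baseline_rate: float = 1.0
    exposure_time: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy(dtype=float)).all():
            raise ValueError("weights must be finite")
        if self.baseline_rate <= 0 or self.exposure_time <= 0:
            raise ValueError("baseline_rate and exposure_time must be positive")

    @classmethod
    def neutral(cls, length: int, positions=None, **kw) -> "SpecificityModel":
        cols = list(positions) if positions is not None else list(range(length))
        df = pd.DataFrame(0.0, index=list(ROW_ORDER), columns=cols)
        return cls(df, **kw)

    @classmethod
    def from_preferences(cls, length: int, preferences: dict, positions=None, **kw) -> "SpecificityModel":
        """Build a model from a sparse {(position, residue): weight} map."""
        model = cls.neutral(length, positions=positions, **kw)
        for (pos, res), w in preferences.items():
            model.weights.loc[res, pos] = float(w)
        return model

    def weight_sum(self, peptide: str) -> float:
        cols = list(self.weights.columns)
        return float(sum(self.weights.loc[aa, cols[j]] for j, aa in enumerate(peptide)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "baseline_rate": self.baseline_rate,
                    "exposure_time": self.exposure_time,
                    "positions": [int(c) for c in self.weights.columns],
                    "weights": {aa: self.weights.loc[aa].tolist() for aa in self.weights.index},
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SpecificityModel":
        with open(path) as fh:
            d = json.load(fh)
        df = pd.DataFrame(d["weights"]).T
        df.columns = d["positions"]
        return cls(df.loc[list(ROW_ORDER)], d["baseline_rate"], d["exposure_time"])


@dataclass
class SimulationConfig:
    design: LibraryDesign
    n_cells: int = 100_000
    reads_per_sample: int = 100_000
    capture_efficiency: float = 0.9
    background_capture: float = 0.01
    sequencing_error_rate: float = 0.0
    abundance_dispersion: float = 0.0
    read_length: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("capture_efficiency", "background_capture", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells < 1 or self.reads_per_sample < 1:
            raise ValueError("n_cells and reads_per_sample must be positive")
        if self.abundance_dispersion < 0:
            raise ValueError("abundance_dispersion must be nonnegative")


def phosphorylation_probability(peptide: str, model: SpecificityModel) -> float:
    """Reaction extent for one peptide: ``1 - exp(-k0 t exp(sum w))``."""
    if len(peptide) != len(model.weights.columns):
        raise ValueError("peptide length does not match the model")
    rate = model.baseline_rate * model.exposure_time * np.exp(model.weight_sum(peptide))
    return float(1.0 - np.exp(-rate))


def _rate_factors(peptides: list, model: SpecificityModel) -> np.ndarray:
    """exp(sum of weights) per peptide, vectorized."""
    W = model.weights.to_numpy(dtype=float)
    row_index = {aa: i for i, aa in enumerate(model.weights.index)}
    sums = np.zeros(len(peptides))
    for n, pep in enumerate(peptides):
        s = 0.0
        for j, aa in enumerate(pep):
            s += W[row_index[aa], j]
        sums[n] = s
    return np.exp(sums)


def _scanning_support(design: LibraryDesign, include_amber: bool = True):
    """Peptides and NNS-multiplicity base weights for a scanning pool."""
    ref = design.reference_peptide
    support: dict = {}
    mult = {aa: len(c) for aa, c in _NNS_BY_RESIDUE.items()}
    for j in range(len(ref)):
        for aa in ROW_ORDER:
            if aa == AMBER and not include_amber:
                continue
            pep = ref[:j] + aa + ref[j + 1:]
            support[pep] = support.get(pep, 0) + mult[aa]
    return support


def sample_library(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> dict:
    """Draw a finite cell population (peptide -> cell count).

    Defined: all members; scanning: reference + single mutants (incl.
    amber variants), weighted by NNS codon multiplicity; degenerate:
    iid NNS-consistent peptides. Log-normal abundance skew with the
    configured dispersion is applied multiplicatively.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    design = config.design
    if design.kind == "degenerate":
        L = design.peptide_length
        rand_pos = [i for i in range(L) if not (design.central_fixed and i == design.central_fixed[0])]
        aa_arr = np.array(_NNS_AA)
        draws = rng.integers(0, len(aa_arr), size=(config.n_cells, len(rand_pos)))
        pop: dict = {}
        fixed = design.central_fixed[1] if design.central_fixed else None
        for row in aa_arr[draws]:
            it = iter(row)
            pep = "".join(next(it) if i in rand_pos else fixed for i in range(L))
            pop[pep] = pop.get(pep, 0) + 1
        if config.abundance_dispersion > 0:
            pop = _apply_dispersion(pop, config, rng)
        return pop
    if design.kind == "scanning":
        weights = _scanning_support(design)
    else:
        weights = {m: 1 for m in design.members}
    peptides = sorted(weights)
    w = np.array([weights[p] for p in peptides], dtype=float)
    if config.abundance_dispersion > 0:
        w = w * rng.lognormal(0.0, config.abundance_dispersion, size=len(w))
    counts = rng.multinomial(config.n_cells, w / w.sum())
    return {p: int(c) for p, c in zip(peptides, counts) if c > 0}


def _apply_dispersion(pop: dict, config: SimulationConfig, rng: np.random.Generator) -> dict:
    peptides = sorted(pop)
    w = np.array([pop[p] for p in peptides], dtype=float)
    w = w * rng.lognormal(0.0, config.abundance_dispersion, size=len(w))
    counts = rng.multinomial(config.n_cells, w / w.sum())
    return {p: int(c) for p, c in zip(peptides, counts) if c > 0}


def calibrate_exposure(
    model: SpecificityModel,
    population: dict,
    target_fraction: float,
    tolerance: float = 0.005,
) -> float:
    """Exposure time at which the population-mean phosphorylation
    extent equals ``target_fraction`` (monotone root search)."""
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    peptides = sorted(population)
    cells = np.array([population[p] for p in peptides], dtype=float)
    cells /= cells.sum()
    rates = model.baseline_rate * _rate_factors(peptides, model)
    if rates.max() <= 0:
        raise ValueError("model gives zero rate for every peptide")

    def mean_extent(t: float) -> float:
        return float(np.sum(cells * (1.0 - np.exp(-rates * t))))

    lo, hi = 1e-12, 1.0
    while mean_extent(hi) < target_fraction:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("target phosphorylation fraction unattainable")
    t = brentq(lambda t: mean_extent(t) - target_fraction, lo, hi, xtol=1e-12, rtol=1e-12)
    if abs(mean_extent(t) - target_fraction) > tolerance:
        raise RuntimeError("root search failed to reach the target fraction")
    return float(t)


def simulate_selection(
    population: dict,
    model: SpecificityModel,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict, dict]:
    """One selection round: Bernoulli phosphorylation per cell, then
    Bernoulli capture. Returns (sorted population, unsorted population);
    unsorted is the input population itself."""
    if not population:
        raise ValueError("population is empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    peptides = sorted(population)
    counts = np.array([population[p] for p in peptides], dtype=np.int64)
    rates = model.baseline_rate * model.exposure_time * _rate_factors(peptides, model)
    p_phos = 1.0 - np.exp(-rates)
    n_phos = rng.binomial(counts, p_phos)
    captured = rng.binomial(n_phos, config.capture_efficiency)
    captured += rng.binomial(counts - n_phos, config.background_capture)
    sorted_pop = {p: int(c) for p, c in zip(peptides, captured) if c > 0}
    return sorted_pop, dict(population)


def expected_enrichment(population: dict, model: SpecificityModel, config: SimulationConfig) -> dict:
    """Closed-form expected enrichment per peptide: capture probability
    ``p_i*c + (1-p_i)*b`` normalized by the population-mean capture."""
    peptides = sorted(population)
    counts = np.array([population[p] for p in peptides], dtype=float)
    rates = model.baseline_rate * model.exposure_time * _rate_factors(peptides, model)
    p = 1.0 - np.exp(-rates)
    cap = p * config.capture_efficiency + (1.0 - p) * config.background_capture
    mean_cap = float(np.sum(counts * cap) / counts.sum())
    return {pep: float(c / mean_cap) for pep, c in zip(peptides, cap)}


def reverse_translate(peptide: str, design: LibraryDesign, rng: np.random.Generator) -> str:
    """Design-consistent codons for a peptide.

    Degenerate positions draw a random NNS codon for the residue; fixed
    positions use the design's codons (central codon, reference codons,
    or the default codon table for defined pools).
    """
    codons = []
    if design.kind == "scanning":
        ref = design.reference_peptide
        for j, aa in enumerate(peptide):
            if aa == ref[j]:
                codons.append(design.reference_codons[j])
            else:
                pool = _NNS_BY_RESIDUE[aa]
                codons.append(pool[rng.integers(0, len(pool))])
    elif design.kind == "degenerate":
        for j, aa in enumerate(peptide):
            if design.central_fixed and j == design.central_fixed[0]:
                codons.append(design.central_codon)
            else:
                pool = _NNS_BY_RESIDUE[aa]
                codons.append(pool[rng.integers(0, len(pool))])
    else:
        codons = [DEFAULT_CODON_TABLE[aa] for aa in peptide]
    return "".join(codons)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def emit_fastq(
    population: dict,
    design: LibraryDesign,
    config: SimulationConfig,
    out_prefix,
    rng: Optional[np.random.Generator] = None,
    gzip_output: bool = False,
) -> dict:
    """Sample reads from a population and write paired FASTQ + truth.

    Each read is an amplicon with random 6-mers at the N positions, the
    constant anchors and flanks, and a design-consistent coding
    sequence; R1/R2 are the two 75-nt ends (overlapping over the
    insert), with substitution errors at the configured rate.
    Returns paths {"r1", "r2", "truth"}.
    """
    if config.reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    peptides = sorted(population)
    counts = np.array([population[p] for p in peptides], dtype=float)
    read_counts = rng.multinomial(config.reads_per_sample, counts / counts.sum())

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    r1_path = out_prefix.with_name(out_prefix.name + "_R1" + suffix)
    r2_path = out_prefix.with_name(out_prefix.name + "_R2" + suffix)
    truth_path = out_prefix.with_name(out_prefix.name + "_truth.tsv")

    if gzip_output:
        import gzip as _gzip

        open_out = lambda p: _gzip.open(p, "wt")
    else:
        open_out = lambda p: open(p, "w")

    qual = "I" * config.read_length
    base_arr = "ACGT"
    n_read = 0
    with open_out(r1_path) as f1, open_out(r2_path) as f2:
        for pep, n_reads in zip(peptides, read_counts):
            for _ in range(int(n_reads)):
                coding = reverse_translate(pep, design, rng)
                n5 = "".join(base_arr[i] for i in rng.integers(0, 4, size=6))
                n3 = "".join(base_arr[i] for i in rng.integers(0, 4, size=6))
                amplicon = (
                    n5 + UPSTREAM_CONST + design.five_flank + coding.upper()
                    + design.three_flank + DOWNSTREAM_CONST + n3
                )
                r1 = amplicon[: config.read_length]
                r2 = _revcomp(amplicon)[: config.read_length]
                r1 = _inject_errors(r1, config.sequencing_error_rate, rng)
                r2 = _inject_errors(r2, config.sequencing_error_rate, rng)
                n_read += 1
                rid = f"sim_{n_read}_{pep}"
                f1.write(f"@{rid}/1\n{r1}\n+\n{qual[:len(r1)]}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{qual[:len(r2)]}\n")
    with open(truth_path, "w") as fh:
        fh.write("peptide\treads\tcells\n")
        for pep, n_reads in zip(peptides, read_counts):
            if n_reads > 0:
                fh.write(f"{pep}\t{int(n_reads)}\t{population[pep]}\n")
    return {"r1": r1_path, "r2": r2_path, "truth": truth_path}


def simulate_screen(
    config: SimulationConfig,
    model: SpecificityModel,
    out_dir,
    sample_prefix: str = "screen",
    gzip_output: bool = False,
) -> dict:
    """Library -> selection -> paired FASTQ for a sorted/unsorted pair.

    All randomness derives from ``config.seed`` through spawned
    generator streams, so identical configs give byte-identical output.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_lib, rng_sel, rng_s, rng_u = (np.random.default_rng(s) for s in seeds)
    population = sample_library(config, rng_lib)
    sorted_pop, unsorted_pop = simulate_selection(population, model, config, rng_sel)
    out_dir = Path(out_dir)
    sorted_files = emit_fastq(
        sorted_pop, config.design, config, out_dir / f"{sample_prefix}_sorted", rng_s, gzip_output
    )
    unsorted_files = emit_fastq(
        unsorted_pop, config.design, config, out_dir / f"{sample_prefix}_unsorted", rng_u, gzip_output
    )
    return {
        "population": population,
        "sorted_population": sorted_pop,
        "unsorted_population": unsorted_pop,
        "sorted_files": sorted_files,
        "unsorted_files": unsorted_files,
    }
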