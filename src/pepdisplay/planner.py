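"""Quantitative planning arithmetic for the sequencing workflow.

Covers the protocol's bench math: converting DNA mass concentration to
molarity (660 g/mol per base pair of double-stranded DNA), serial
dilution bookkeeping for Illumina loading prep, sequencing depth and
multiplexing capacity, and the final loading-mix composition (sample +
PhiX spike + diluent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

DSDNA_G_PER_MOL_PER_BP = 660.0


@dataclass
class DnaSample:
    mass_concentration: float  # ng/uL
    length_bp: int

    def __post_init__(self) -> None:
        if self.mass_concentration <= 0 or self.length_bp <= 0:
            raise ValueError("mass concentration and length must be positive")

    @property
    def molar_concentration_nM(self) -> float:
        return mass_to_molar(self.mass_concentration, self.length_bp)


def mass_to_molar(mass_conc_ng_per_ul: float, length_bp: float) -> float:
    """ng/uL -> nM for double-stranded DNA:
    ``(mass / (length x 660)) x 10^6``."""
    if mass_conc_ng_per_ul <= 0 or length_bp <= 0:
        raise ValueError("inputs must be positive")
    return (mass_conc_ng_per_ul / (length_bp * DSDNA_G_PER_MOL_PER_BP)) * 1e6


def molar_to_mass(molar_nM: float, length_bp: float) -> float:
    """Inverse of :func:`mass_to_molar` (nM -> ng/uL)."""
    if molar_nM <= 0 or length_bp <= 0:
        raise ValueError("inputs must be positive")
    return molar_nM * length_bp * DSDNA_G_PER_MOL_PER_BP / 1e6


def dilution_series(steps: Sequence[tuple]) -> float:
    """Overall concentration factor of serial dilutions.

    Each step is ``(volume_added, volume_carried)``; the factor
    multiplies by ``carried / (carried + added)`` per step. E.g. mixing
    2 uL sample with 3 uL water is step ``(3, 2)`` -> factor 0.4.
    """
    factor = 1.0
    for added, carried in steps:
        if added < 0 or carried <= 0:
            raise ValueError("carried volume must be positive, added nonnegative")
        factor *= carried / (carried + added)
    return factor


def dilute(concentration: float, steps: Sequence[tuple]) -> float:
    """Concentration after serial dilution steps."""
    return concentration * dilution_series(steps)


@dataclass
class DepthPlan:
    """Sequencing depth / multiplexing capacity.

    For defined libraries the protocol targets 200-500 reads per
    sequence in an unsorted sample, so a 10,000-sequence library at 200
    reads needs 2 million reads per sample, and a 20-30 million-read
    kit multiplexes 10-15 samples.
    """

    library_size: int
    reads_per_variant: int
    kit_yield: int

    def __post_init__(self) -> None:
        if min(self.library_size, self.reads_per_variant, self.kit_yield) < 1:
            raise ValueError("all inputs must be positive integers")

    @property
    def per_sample_reads(self) -> int:
        return self.library_size * self.reads_per_variant

    @property
    def max_samples(self) -> int:
        return self.kit_yield // self.per_sample_reads


def depth_plan(library_size: int, reads_per_variant: int, kit_yield: int) -> DepthPlan:
    return DepthPlan(library_size, reads_per_variant, kit_yield)


@dataclass
class LoadingMix:
    sample_volume: float
    spike_volume: float
    diluent_volume: float

    @property
    def total_volume(self) -> float:
        return self.sample_volume + self.spike_volume + self.diluent_volume


def loading_mix(
    target_conc: float,
    target_volume: float,
    spike_fraction: float,
    stock_sample: float,
    stock_spike: float,
) -> LoadingMix:
    """Volumes of pooled sample, spike (PhiX) and diluent for a loading
    mix of ``target_conc`` total DNA with a molar ``spike_fraction``.

    All concentrations share one unit (typically pM). Raises when a
    stock is too dilute to reach its share of the target, naming the
    limiting component.
    """
    if not 0.0 <= spike_fraction <= 1.0:
        raise ValueError("spike_fraction must be in [0, 1]")
    if target_conc <= 0 or target_volume <= 0 or stock_sample <= 0:
        raise ValueError("concentrations and volumes must be positive")
    sample_share = (1.0 - spike_fraction) * target_conc * target_volume
    spike_share = spike_fraction * target_conc * target_volume
    v_sample = sample_share / stock_sample
    v_spike = spike_share / stock_spike if spike_share > 0 else 0.0
    v_diluent = target_volume - v_sample - v_spike
    if v_sample > target_volume + 1e-9:
        raise ValueError("infeasible target: pooled-sample stock is too dilute")
    if v_spike > target_volume + 1e-9 or v_diluent < -1e-9:
        limiting = "spike" if v_spike > v_sample else "pooled sample"
        raise ValueError(f"infeasible target: {limiting} stock is too dilute")
    return LoadingMix(v_sample, v_spike, max(v_diluent, 0.0))
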