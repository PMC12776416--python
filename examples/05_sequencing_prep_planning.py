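"""Sequencing-prep arithmetic: molarity, dilutions, depth, loading mix.

Reproduces the planning numbers for a 10,000-sequence phosphosite
library run on a 30-million-read kit, and the Illumina denature-and-
dilute concentrations.
"""

from pepdisplay import depth_plan, dilute, loading_mix, mass_to_molar

# A 255-bp amplicon quantified at 20 ng/uL:
nM = mass_to_molar(20, 255)
print(f"20 ng/uL of a 255-bp amplicon = {nM:.1f} nM")

# PhiX control: 2 uL of 10 nM stock + 3 uL water
print(f"PhiX diluted: {dilute(10.0, [(3, 2)]):.1f} nM")

# Pooled DNA: 5 uL at 4 nM + 5 uL NaOH, then + 990 uL HT1 buffer
final = dilute(4.0, [(5, 5), (990, 10)])
print(f"denatured pool: {final * 1000:.1f} pM")

# Depth: 10,000 sequences x 200 reads each, 30M-read kit
plan = depth_plan(10_000, 200, 30_000_000)
print(f"per-sample reads: {plan.per_sample_reads:,}; "
      f"samples multiplexable: {plan.max_samples}")

# Loading mix: 600 uL at 12 pM with a 5% PhiX spike, both stocks 20 pM
mix = loading_mix(12, 600, 0.05, 20, 20)
print(f"loading mix: {mix.sample_volume:.0f} uL sample + "
      f"{mix.spike_volume:.0f} uL PhiX + {mix.diluent_volume:.0f} uL buffer")
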