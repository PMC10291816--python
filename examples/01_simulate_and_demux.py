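"""Simulate a spike-in sequencing run and demultiplex it.

Builds a 260-template barcode library, emits barcode-bearing ST reads plus
CDR3-bearing clonotype reads for one mixed sample, and separates them again
with single-edit barcode matching.
"""

import otsp
from otsp.simulate import SimConfig, emit_reads, simulate_experiment, simulate_repertoire

library = otsp.generate_barcode_library(seed=1)
model = otsp.make_bias_model(seed=2)
truth, pmap = simulate_repertoire(n_clones=30, sigma=1.0, seed=3)

config = SimConfig(seed=4, depth=6000, st_mass=1.0, gdna_mass=1.0, error_rate=0.001)
observed, st_counts = simulate_experiment(truth, model, config)
reads = emit_reads(st_counts, observed, library, config)

counts, clonotype_reads, summary = otsp.demux_sample(reads, library)

print(f"reads in:            {summary.n_reads}")
print(f"  spike-in (ST):     {summary.n_st}")
print(f"  clonotype:         {summary.n_clonotype}")
print(f"  ambiguous:         {summary.n_ambiguous}")
recovered = counts.sum() / st_counts.sum()
print(f"ST reads assigned to a template: {100 * recovered:.2f}%")
v, j = counts.idxmax()
print(f"most abundant template: V{int(v)}/J{int(j)} with {int(counts.max())} reads")
# The three classes always sum to the input; at error rate ~1e-3 nearly
# every ST read is still assignable within one barcode edit, and at error
# rate 0 the per-template counts round-trip exactly.
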