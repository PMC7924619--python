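"""Generate a synthetic pupylation-window dataset with planted signal.

Builds 200 positive and 200 negative 57-residue lysine-centered windows.
Positives enrich R, Y and L at several offsets (and deplete P and K at
one offset each) relative to the uniform background the negatives are
drawn from — the same structure a two-sample logo of real pupylation
sites shows.
"""

from pupfuse import write_manifest
from pupfuse.synthetic_data import default_planted_config, generate

config = default_planted_config(n_pos=200, n_neg=200, effect=0.3, seed=7)
dataset = generate(config)

print(f"{len(dataset)} windows, ratio {dataset.ratio}, seed {dataset.seed}")
print("first positive:", dataset.windows[0].residues)
print("first negative:", dataset.windows[200].residues)
print("planted effects:")
for e in config.planted_effects:
    print(f"  {e.sign:>7} {e.residue} at offset {e.offset:+d} (delta {e.delta:.3f})")

write_manifest(dataset, "sim.manifest.tsv")
print("manifest written to sim.manifest.tsv "
      "(protein_id, position, label, window per row)")
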