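"""Simulate a five-condition overexpression experiment with planted truth.

Generates a count matrix (control + four overexpression conditions in
triplicate) in which a shared core of genes is up- or down-regulated in
every overexpression condition, plus per-condition extras, and prints
what was planted.
"""

from txsig import SimConfig, generate_counts

config = SimConfig(n_genes=5000, n_shared_up=60, n_shared_down=90,
                   n_specific=20, seed=42)
counts, truth = generate_counts(config)

print(f"count matrix: {counts.n_genes} genes x {counts.n_samples} samples")
print(f"conditions: {counts.condition_labels()}")
print(f"planted shared up / down: {len(truth.shared_up)} / {len(truth.shared_down)}")
for cond, (up, down) in sorted(truth.specific.items()):
    print(f"  {cond}: {len(up)} specific up, {len(down)} specific down")
print(f"planted fold change: 2^{truth.base_log2fc} = {2 ** truth.base_log2fc:.3f}, "
      f"NB dispersion {truth.dispersion}")
# The truth object is the oracle every downstream example checks against.
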