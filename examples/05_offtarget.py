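"""Screen a guide for off-target effects.

Sequence similarity (Hamming windows over both strands) proposes candidate
genes; a candidate is only reported if its expression correlation with the
intended target *increases* in perturbed cells versus controls (one-sided
Fisher z), the signature of a shared knockout.
"""

import numpy as np

import topicscreen as ts
from topicscreen.offtarget import reverse_complement

rng = np.random.default_rng(2)
guide = "ACGTTGCAACGTTGCAACGT"
bases = np.array(list("ACGT"))

transcripts = {f"G{i:04d}": "".join(rng.choice(bases, 120)) for i in range(1, 6)}
# plant a 1-mismatch site on the reverse strand of G0003
site = list(guide)
site[9] = "A" if site[9] != "A" else "C"
transcripts["G0003"] = (transcripts["G0003"][:40]
                        + reverse_complement("".join(site))
                        + transcripts["G0003"][40:])

candidates = ts.find_candidates(guide, transcripts, target_gene="G0001",
                                max_mismatch=3, sgrna_id="sg1")
print("sequence candidates (gene, mismatches, strand):")
for c in candidates:
    print(f"  {c.candidate_gene}: {c.mismatches} mm, strand {c.strand}")

# an expression dataset where the G0003 candidate co-varies with the target
# in perturbed cells only
n = 60
target = rng.normal(10, 2, 2 * n)
g3 = np.where(np.arange(2 * n) < n, target + rng.normal(0, 0.5, 2 * n),
              rng.normal(10, 2, 2 * n))
counts = np.clip(np.column_stack(
    [target, rng.normal(10, 2, 2 * n), g3]), 0, None)
dataset = ts.ScreenDataset(
    counts=counts,
    cell_ids=np.asarray([f"c{i}" for i in range(2 * n)], dtype=object),
    gene_ids=np.asarray(["G0001", "G0002", "G0003"], dtype=object),
    perturbation=np.asarray(["G0001"] * n + ["CTRL"] * n, dtype=object))

report = ts.correlation_increase_test(dataset, "G0001", candidates)
print("\ncorrelation-increase test (flagged = correlation rose in the "
      "perturbed cells):")
print(report.round(3).to_string(index=False))
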