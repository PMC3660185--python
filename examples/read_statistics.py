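"""Per-run read statistics and length-weighted aggregation.

Synthesizes two read sets of different sizes, computes streaming FASTA
statistics for each, and combines them the way sequencing runs must be
combined: counts and lengths sum, the mean is length-weighted.
"""

import tempfile
from pathlib import Path

import pooldiff as pdx

tmp = Path(tempfile.mkdtemp())
truth = pdx.simulate_truth(pdx.SimParams(seed=1))
pdx.synthesize_reads(truth, 2000, tmp / "run1.fa")
truth2 = pdx.simulate_truth(pdx.SimParams(seed=2))
pdx.synthesize_reads(truth2, 500, tmp / "run2.fa")

runs = [pdx.read_statistics(tmp / f"run{i}.fa") for i in (1, 2)]
for i, r in enumerate(runs, 1):
    print(f"run{i}: n={r.n_reads}  total={r.total_length} bp  "
          f"mean={r.mean_length:.1f}  min={r.min_length}  max={r.max_length}")
combined = pdx.aggregate_runs(runs)
print(f"combined: n={combined.n_reads}  mean={combined.mean_length:.1f} bp "
      f"(length-weighted, not the mean of the two means)")

counts = [8000, 3500, 1800]
lengths = [100_000, 45_000, 20_000]
r = pdx.chromosome_read_correlation(counts, lengths)
print(f"\nreads-per-chromosome vs chromosome length: Pearson R = {r:.2f}")
print("R near 1 means reads spread over chromosomes in proportion to size.")
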