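"""Predict a replication timing profile from a genomic signal track.

Builds a small bedgraph of open-chromatin-like signal, converts it to an
initiation probability landscape, simulates a cell population, and prints
the per-bin expected replication time.  Early-replicating bins (near strong
signal peaks) get small mean sweeps; late bins get large ones.
"""

import numpy as np

import forksim as fs

# synthetic DNase-like signal: two strong peaks and one weak one
rng = np.random.default_rng(0)
with open("/tmp/signal.bedgraph", "w") as fh:
    for i in range(60):
        x = 4.0 * np.exp(-0.5 * ((i - 12) / 3) ** 2)
        x += 3.5 * np.exp(-0.5 * ((i - 45) / 3) ** 2)
        x += 1.0 * np.exp(-0.5 * ((i - 30) / 2) ** 2)
        fh.write(f"chrDemo\t{i * 500}\t{(i + 1) * 500}\t{x:.4f}\n")

landscape = fs.bedgraph_to_ipls("/tmp/signal.bedgraph", binsize=500)
print(f"landscape: {landscape.n_bins} bins, max prob at bin "
      f"{landscape.init_prob.argmax()}")

config = fs.SimulationConfig(
    ncells=200, nfork=6, ntherm=100, nmeas=10, stepsize=30, seed=1
)
record = fs.run_simulation(config, landscape)
profile = fs.timing_profile(record)

print(f"completed S phases observed: {record.n_cycles}")
print("bin  start_bp  mean_sweep  normalized")
for b in range(0, 60, 6):
    print(f"{b:3d}  {b * 500:8d}  {profile.mean_sweep[b]:10.2f}  "
          f"{profile.normalized[b]:+10.2f}")
# mean_sweep: expected sweeps after S entry until the bin replicates
# (x 10 s/sweep at 500 bp bins); normalized: z-scored, early = positive.
print(f"\nearliest bin: {profile.mean_sweep.argmin()} "
      f"(near the strongest initiation peak)")
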