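# forksim

Stochastic simulation of DNA replication timing in metazoan cells.

Eukaryotic genomes replicate on a strict temporal program, yet in metazoa
no comprehensive catalog of replication origins exists and models that
assign per-origin firing times need hundreds of thousands of parameters.
forksim takes the opposite approach: timing is an *emergent* property of a
minimal stochastic mechanism with a single technical constant.  An ensemble
of independent virtual cells replicates a binned chromosome using a fixed
pool of replication forks; initiation sites are drawn at random and fire
according to an **initiation probability landscape (IPLS)** — typically
derived from open-chromatin (DNase hypersensitivity) signal — and forks
synthesize bidirectionally at a constant 50 bp/s until they collide or
reach a chromosome end.  The per-bin expectation of replication time over
the ensemble is the predicted timing profile.

The package is aimed at researchers who want to predict replication timing
for cell types where only chromatin accessibility (or any other genomic
signal hypothesized to localize initiation) is available, and at modelers
studying replication kinetics: alongside timing profiles it simulates the
classic measurement devices — flow-sorted (Repli-seq style) fractions, DNA
combing (eye / hole / eye-to-eye statistics), nascent-strand origin
profiles, global initiation rates, and population phase indices.

## Model in brief

Per cell, per discrete sweep (one sweep = `binsize`/50 bp/s = 10 s at
500 bp bins):

1. engaged forks advance one bin with probability *p*<sub>progress</sub>
   (default 1), disengaging on collision with replicated DNA or at
   chromosome ends;
2. engaged forks release with probability *p*<sub>release</sub> (default 0);
3. for each free fork pair, a uniformly random unreplicated bin fires with
   its IPLS probability, engaging a bidirectional fork pair there;
4. when the chromosome is fully replicated the cell re-enters G rest for a
   normally distributed interval, then starts a new S phase.

See `docs/methods.md` for the full specification of conventions,
tie-breaks and design choices.

## Worked example

`examples/predict_timing.py` builds a small synthetic open-chromatin
bedgraph with two strong peaks (bins 12 and 45) and one weak one (bin 30),
converts it to an IPLS, simulates 200 cells and prints the timing profile:

```
landscape: 60 bins, max prob at bin 12
completed S phases observed: 1397
bin  start_bp  mean_sweep  normalized
  0         0       13.54       -1.51
  6      3000        7.66       +0.44
 12      6000        4.45       +1.50
...
earliest bin: 12 (near the strongest initiation peak)
```

`mean_sweep` is the expected number of sweeps after S entry until the bin
replicates (multiply by 10 s for wall-clock time at 500 bp bins);
`normalized` is the z-scored, early-positive form used for comparison with
early/late-ratio timing data.  The strongest initiation peak replicates
earliest; timing rises smoothly with distance from initiation zones — the
emergent timing program.

Other examples: `combing_experiment.py` (eye lengths grow from ~2.0 kb in
early S to >20 kb in late S while holes shrink, as in single-molecule
combing), `flow_sort_and_rates.py` (flow-sorted gates and initiation
rates), `fork_velocity.py` (recovers 50 bp/s per fork exactly from eye
growth).

A command-line interface mirrors the canonical parameter set:

```sh
forksim chr14.ipls --timing --flow-sorter 0,0.25,0.5,0.75,1 \
    --ncells 1000 --nfork 50 -o chr14
```

writes `chr14.timing.bedgraph`, `chr14.flowsort.tsv`, … (one chromosome per
invocation; IPLS files are 2–4 column text: position, initiation
probability, optional per-bin fork-progress and fork-release).

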