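# forkrestart

Quantification of homologous-recombination–mediated replication restart at a
polar replication fork barrier (RFB) from **Pu-Seq** (polymerase-usage
sequencing) data, together with a forward stochastic simulator that generates
fully ground-truthed synthetic inputs.

## The problem

In fission yeast, the *RTS1* barrier arrests replication forks arriving from
one direction only. Arrested forks are resected (~1 kb), and most restart
~20 minutes later by recombination-dependent replication (RDR). Restarted
synthesis is non-canonical: **both** strands are made by Pol δ, whereas a
canonical fork splits the work (leading strand Pol ε, lagging strand Pol δ).
Pu-Seq reads this signature out genome-wide: ribonucleotides
hyper-incorporated by mutant Pol δ or Pol ε (in a ribonucleotide-excision
deficient background) are mapped strand-specifically, giving per-strand
polymerase usage fractions.

## The statistic

With `U_δ^W(x)`, `U_δ^C(x)` the Pol δ usage on the Watson/Crick strands, the
**δ/δ bias** is

```
b(x) = ( U_δ^W(x) + U_δ^C(x) ) / 2
```

`b = 0.5` under canonical replication and `b = 1` where every cell's fork was
restarted. Immediately downstream of the barrier the bias increment is a
linear read-out of the restart fraction

```
f = (b_prox − b0) / (1 − b0)        (b = 1 ⇒ 100% restarted, b = 0.5 ⇒ 0%)
```

with the baseline `b0` estimated from an upstream window. Restarted-fork
progression is summarized by the **half-distance** `d_half`: the distance
downstream at which the bias increment first falls to half its proximal
value — slow restarted forks terminate against the converging canonical fork
closer to the barrier, shrinking `d_half`. Confidence intervals come from a
moving-block bootstrap over genomic bins that re-estimates the baseline
calibration in every resample.

The simulator (`forkrestart.simulate`) replicates a two-origin, 60 kb locus
cell by cell with event-driven kinematics: truncated-normal origin firing,
polar arrest with probability `p_block`, restart with probability `p_restart`
after delay `T` from `barrier − resection_len` at speed `v_r`, rescue of
non-restarted arrests by the converging fork, and Poisson sequencing noise
with background incorporation `β`. It records the realized restart fraction,
so every estimator can be validated against ground truth.

## Worked example

```
python examples/01_simulate_dataset.py
python examples/03_quantify_restart.py
```

prints (seed 1, generator defaults):

```
baseline bias b0:        0.5001   (0.5 = canonical replication)
proximal bias b_prox:    0.8975
estimated background:    0.0505
restart fraction f:      0.7949   95% CI [0.7777, 0.8137]
ground truth (realized): 0.8058
progression d_half:      9425 bp downstream
```

The estimator recovers the realized restart fraction (80.6% of cells) within
its CI, the calibration recovers the configured 5% background incorporation,
and restarted forks progress ~9–10 kb before half of them have terminated.
`examples/02_polymerase_usage.py` shows the strand-level usage switch at the
barrier and `examples/04_compare_strains.py` contrasts a restart-initiation
mutant (relative restart ≈ 0.63, progression ≈ 1) with a slow-progression
mutant (restart ≈ 1, progression ≈ 0.46).

The same pipeline is available as a CLI:

```
forkrestart simulate --config examples/strain_reference.yml --out data/
forkrestart usage --manifest data/manifest.json --out usage/
forkrestart restart --usage-dir usage/ --barrier 30000 --out report.json
forkrestart compare --ref report.json --mut report_mut.json
```

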