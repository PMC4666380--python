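# pcrdistort

Quantitative models of the distortions PCR introduces into low-input
high-throughput sequencing libraries — and estimators that read those
distortions back out of barcode-pair read counts.

When a pool of unique single-copy DNA molecules (e.g. UMI-tagged amplicons,
single-cell libraries) is PCR-amplified and sequenced, the read-count-vs-rank
profile is not the flat plateau naive doubling predicts: a shoulder and a long
tail appear. Four processes can contribute:

* **Stochastic amplification.** Each molecule duplicates each cycle with
  probability `P_amp` (a Galton–Watson branching process,
  `n(j+1) = n(j) + Binomial(n(j), P_amp)`). A molecule that misses the first
  one or two cycles ends up at 1/2 or 1/4 of the typical copy number, which
  leaves local maxima at 0.5× and 0.25× of the global mode of the copy-number
  distribution and creates the shoulder.
* **GC bias.** Per-sequence efficiencies `c_x` estimated from plateau
  abundances via `c_x = (m_x · 1.9^25)^(1/25)`, binned by GC content and
  regressed on it.
* **Template switching.** Chimeric barcode pairs form at rate `s0 · N_j²`
  per cycle (bimolecular collisions). Purine/pyrimidine anchor patterns of
  the two barcode classes expose between-class chimeras; the per-molecule
  switch rate follows from the chimeric read fraction `J_k` as
  `s0 = 2 · J_k / (N0 · c^(k+1))`.
* **Polymerase errors.** With a per-molecule per-cycle error rate `e`, the
  erroneous read fraction after `k` cycles is `F_k = k·e/c`, inverted to
  estimate `e` (and the per-nucleotide rate `e/40`) from the fraction of tail
  sequences one substitution away from the plateau.

The package implements the forward models, the exact and Gaussian-extended
copy-number distributions, all estimators, a bootstrap test for the rank-space
position of switches/errors, and a synthetic paired-end experiment generator
(101-nt reads: 20-nt barcode + 46-nt AttL constant region + 20-nt barcode +
15-nt varietal tag) so that every stage runs end-to-end with no external data.
Real data in the same amplicon design (e.g. SRA accession SRP057767) can be
fed through the same `preprocess` entry point.

## Worked example

```python
import numpy as np
from pcrdistort import exact_pdf, find_modes
from pcrdistort.pipeline import RunConfig, simulate_experiment, analyze_profile

# Mode structure of the copy-number distribution after 4 cycles, P_amp = 0.9
for copies, prob in find_modes(exact_pdf(4, 0.9)):
    print(f"copies {copies:5.0f}   P = {prob:.4f}")

# Full synthetic experiment at study scale and parameter recovery
cfg = RunConfig(seed=1, n_input=2900)   # 25 cycles, P_amp=0.9,
                                        # p_nt=2.7e-5, s0=2.6e-15
est = analyze_profile(simulate_experiment(cfg), cfg)
print(est.p_amp_fit, est.p_nt_hat, est.s0_hat)
```

prints

```
copies    16   P = 0.2059
copies    12   P = 0.1101
copies     8   P = 0.0588
copies     4   P = 0.0086
0.9 2.4890380766738764e-05 2.7916480644212856e-15
```

The first block is the early-cycle multimodality of stochastic PCR: the
global mode at 16 copies (amplified every cycle) with local maxima at 12, 8
and 4. The second block shows the analysis recovering the generating
parameters from the synthetic reads: `P_amp = 0.9` exactly from the candidate
grid, the per-nucleotide polymerase error rate within ~8% of the true
2.7e-5, and the switch rate within ~7% of the true 2.6e-15.

There is also a CLI:

```sh
pcrdistort pdf --cycles 4 --p-amp 0.9
pcrdistort run --seed 1 --outdir results/run1
pcrdistort simulate --seed 1 --outdir sim --fastq
pcrdistort preprocess sim/sim_R1.fastq sim/sim_R2.fastq --out counts.tsv
```

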