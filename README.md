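# chromstates

Chromatin-state segmentation and feature-density reporting for *Drosophila
melanogaster* pericentromeric heterochromatin.

Polytene chromosomes display a reproducible band/interband pattern that
reflects an underlying partition of the genome into a small number of
chromatin states. A widely used description divides the fly genome into four
states inferred from multi-protein occupancy: **Aquamarine** (interbands;
promoters of housekeeping genes, marked by CHRIZ/Chromator), **Lazurite**
(housekeeping-gene bodies, marked by elongation factors such as RNA-polII),
and the condensed band states **Malachite** and **Ruby**. Extending such a
model into the heterochromatic arms (3LHet/3RHet) raises the questions this
package operationalises: how the state mix shifts between euchromatin and
heterochromatin, which proteins are enriched or depleted per state, and how
gene and ORC-site densities fall off across named heterochromatic regions.

`chromstates` provides, as a tested reusable pipeline:

- **`chromstates.intervals`** — BED/bedGraph/chrom.sizes I/O, 0-based
  half-open genomic intervals, and projection onto a fixed-width bin grid
  (200 bp by default).
- **`chromstates.hmm`** — `BernoulliHMM`, a scikit-learn-style estimator
  (`fit` / `predict` / `score` / `sample`) implementing a hidden Markov chain
  over genome bins with independent Bernoulli emissions per binarized track
  (the product-Bernoulli family of chromHMM-style segmentations), trained by
  multi-restart Baum–Welch and decoded by Viterbi; plus state labeling from
  marker emissions and conversion between state paths and BED segmentations.
- **`chromstates.stats`** — per-state genome fractions and per (track, state)
  enrichment against a background compartment, with two-sided Mann–Whitney
  rank-sum significance at a fixed p < 0.001 rule.
- **`chromstates.regions`** — named-region bookkeeping, gene/ORC densities
  per Mb under explicit counting rules, and the eight-level RPKM expression
  binning (ExtremelyHigh > 1000 … ExtremelyLow/None = 0) over 29 tissues.
- **`chromstates.simulate`** — generators for every input with known ground
  truth: HMM-sampled binary track matrices, region-structured annotations
  with Poisson densities, and per-tissue RPKM vectors.
- **`chromstates.cli` / `chromstates.pipeline`** — a `chromstates` command
  with `simulate`, `binarize`, `train`, `segment`, `proportions`, `enrich`,
  `density` and `run-all` subcommands.

## The model

Observations are binarized occupancy calls for M protein/histone-mark tracks
on a grid of fixed-width bins. Hidden states k = 1..K (K = 4) follow a
first-order Markov chain with initial distribution π and transition matrix A;
given state k, track m emits 1 with probability e_km independently of the
other tracks:

    P(x_t | z_t = k) = Π_m e_km^{x_tm} (1 − e_km)^{1 − x_tm}

Training maximises the likelihood by Baum–Welch EM (scaled forward/backward,
probability floors at 1e-6, best of 5 seeded restarts); decoding is Viterbi
with ties broken toward the lowest state index. Masked bins (assembly gaps)
split the chain into independent segments rather than being imputed. The four
states then earn their names from emissions: highest promoter-marker emission
→ Aquamarine; of the rest, highest elongation-marker emission → Lazurite; of
the last two, the more protein-depleted is Ruby, the other Malachite.

## Worked example

Generate a 10-Mb genome of synthetic occupancy from a known 4-state model,
re-train from scratch, label the states and summarise the segmentation:

```python
from chromstates import (
    GeneratorSpec, generate_tracks, train_hmm, label_states,
    viterbi_decode, path_to_segmentation, state_proportions, GenomicInterval,
)

spec = GeneratorSpec(seed=11, chrom_sizes={"chrSim": 10_000_000}, bin_size=200)
matrix, truth_path = generate_tracks(spec)

model = train_hmm(matrix, K=4, seed=17, n_restarts=5)
label_states(model, {"promoter": "CHRIZ", "elongation": "RNA-polII"})

path = viterbi_decode(model, matrix)
seg = path_to_segmentation(path, spec.grid, model.labels_)
props = state_proportions(seg, [GenomicInterval("chrSim", 0, 10_000_000)])
print(f"log-likelihood {model.log_likelihood_:.1f}, {len(seg)} state intervals")
chriz = {v: model.emissionprob_[k, 0] for k, v in model.labels_.items()}
for label in ("Aquamarine", "Lazurite", "Malachite", "Ruby"):
    print(f"{label:>10}: {props.fractions[label]:.3f} of the genome, "
          f"CHRIZ emission {chriz[label]:.2f}")
```

which prints

```
log-likelihood -143217.4, 2024 state intervals
Aquamarine: 0.249 of the genome, CHRIZ emission 0.90
  Lazurite: 0.267 of the genome, CHRIZ emission 0.14
 Malachite: 0.235 of the genome, CHRIZ emission 0.30
      Ruby: 0.248 of the genome, CHRIZ emission 0.05
```

The generating chain is uniform over the four states, and the re-trained
model recovers both the state mix (~0.25 each) and the emission profiles
(CHRIZ high only in Aquamarine) from the data alone.

The same flow from a shell:

```sh
chromstates simulate --seed 17 --n-bins 50000 --out sim/
chromstates run-all --chrom-sizes sim/chrom.sizes --tracks sim/tracks.tsv --out run/
```

Density arithmetic works directly from published counts and lengths — e.g. a
dense euchromatic band with 18 genes in 0.189 Mb (95 genes/Mb) against a
heterochromatin block with 6 genes in 0.797 Mb (7.5 genes/Mb), a ~12.7-fold
contrast:

```sh
printf 'band\t18\t0.189\nblock\t6\t0.797\n' > counts.tsv
chromstates density --counts counts.tsv
```

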