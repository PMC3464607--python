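# sbscall

Particle-filter base calling for sequencing-by-synthesis intensity data.

Illumina-style sequencers read DNA by synthesizing the complementary
strand one cycle at a time and imaging four fluorescence channels (one
per base). The raw per-cluster, per-cycle intensities are corrupted by
*phasing* (a strand fails to extend, probability *p*) and *pre-phasing*
(it extends twice, probability *q*), stochastic decay of the cluster
signal density λ<sub>t</sub>, spectral crosstalk between the dye channels
(a 4×4 matrix *K*), a residual carry-over of a fraction α of the previous
cycle's measurement, and Gaussian noise whose scale follows the signal.
`sbscall` is for people who want to go from such intensities to called
sequences with meaningful per-base quality scores, and for method
developers who need a fully simulatable, testable model of that pipeline.

## Model and algorithms

A length-*L* template is a 4×*L* indicator matrix *S*. Strand lengths
follow a Markov chain with transition probabilities (*p*, 1−*p*−*q*, *q*)
for staying, advancing one, or advancing two states; its powers give the
profile matrix *H* with `H[i,j] = [P^j]_{1,i+1}`, the probability a
strand has length *i* after *j* cycles. The signal and observation model
is

    λ_t | λ_{t-1} ~ N((1-d_t) λ_{t-1}, (1-d_t)^2 λ_{t-1}^2 σ_t^2)
    x_t^w = λ_t S h_t^w                      (h_t windowed to l+r+1 terms)
    y''_t = y_t − α_t (1−d_t) y_{t-1}        (residual correction)
    y''_t | S_t^w, λ_t ~ N(K_t x_t^w, ||x_t^w||² Σ_t)

which is a hidden Markov model whose state is the pair
(S<sub>t</sub><sup>w</sup>, λ<sub>t</sub>): the window of l+r+1 template
columns around position *t* plus the density. Inference is sequential
Monte Carlo:

* **plain SISR filter** — particles carry (S<sub>t</sub><sup>w</sup>, λ<sub>t</sub>),
  proposals come from the model transition, weights from the observation
  density, with multinomial resampling when the effective sample size
  K_eff = (Σ w²)⁻¹ drops to N_p/2;
* **Rao-Blackwellized filter** — the 4^(l+r+1) discrete window states are
  marginalized exactly per particle, so particles track only λ_t and far
  fewer of them are needed;
* **particle-filter EM** — cycle-dependent parameters {α, K, Σ} are
  estimated per window of *w* cycles by EM whose E-step uses equally
  weighted filter trajectories and whose M-step is closed-form weighted
  least squares; decay hyper-moments come from an early-cycle
  initialization where phasing is negligible and x_t ≈ λ_t s_t.

Calls are the per-cycle MAP of the filtered posterior p(s_t | y''_{1:t});
the phred score is −10·log₁₀(1 − posterior of the call), capped at Q60.
A generative simulator produces tiles from the exact (unwindowed) model
with ground truth, so every stage is verifiable without instrument data.

## Worked example

```python
import sbscall as sc

params = sc.default_preset(L=76)                 # realistic noisy preset
tile   = sc.simulate_tile(n=200, L=76, params=params, seed=42)

plain = sc.call_tile(tile.reads, params, N_p=800, seed=1)
rb    = sc.rb_call_tile(tile.reads, params, N_p=300, seed=2)
naive = [sc.naive_call(rd, params) for rd in tile.reads]

for name, calls in [("plain", [r.calls for r in plain]),
                    ("rb",    [r.calls for r in rb]),
                    ("naive", naive)]:
    print(name, sc.error_rate(calls, tile.truths)[0])
```

prints (exactly, for these seeds):

```
plain 0.013092105263157894
rb    0.012894736842105263
naive 0.02144736842105263
```

Both filters land within 0.0002 of each other — the Rao-Blackwellized
variant with 300 particles matches the plain filter with 800 — and both
roughly halve the error rate of per-cycle argmax calling. The
`examples/` directory has one narrative script per capability
(simulation, calling, parameter estimation, quality scores); each prints
its numbers with a line on what they mean.

The same pipeline is available from the shell:

```bash
sbscall simulate --config sim.yaml --seed 3 --out-intensities tile.tsv --out-fasta truth.fasta
sbscall estimate --intensities tile.tsv --p 1e-7 --q 0.003 --out params.yaml
sbscall call     --intensities tile.tsv --params params.yaml --out calls.fastq
sbscall evaluate --fastq calls.fastq --truth truth.fasta --out-prefix eval
```

The intensity table is a TSV with columns `cluster_id  cycle  A  C  G  T`
(cycles contiguous from 1); calls are written as phred+33 FASTQ.

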