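# rfctx — context models vs. multifilter LN models for spiking neurons

`rfctx` is a Python toolkit for estimating and comparing receptive-field
models of spiking sensory neurons driven by binary bar stimuli, of the kind
recorded from complex cells in primary visual cortex (16 pseudo-random bars
refreshed at 60 Hz, per-frame spike counts).

Two model families are implemented end to end:

* **Context models** — a single receptive field (RF) whose elements are
  multiplicatively gated by the local stimulus context through one or more
  context fields (CFs):

      z_i = w0 + Σ_l Σ_{j∈ctx_l} w_j^rf x_ij (1 + Σ_k w_k^{cf_l} x̃_ijk)

  fitted by an alternating convex-subproblem algorithm with linear, logistic
  or Poisson subproblem families (identity / logistic / exponential output
  nonlinearities), Tikhonov (l2 or discrete-Laplacian) regularization and
  cross-validated regularization strength.

* **Multifilter LN models** — spike-triggered covariance (STC) subspaces,
  information-theoretic STA/STC (iSTAC), low-rank maximum-noise-entropy
  quadratic models (MNE), and direct information maximization (MID) that
  refines any of them by gradient ascent on the single-spike information

      I = Σ_z P(z|spike) log2[ P(z|spike) / P(z) ]   (bits per spike).

Model quality is measured as bias-corrected single-spike information on
held-out data (null-feature and quadratic-extrapolation corrections, with
resolution averaging over 25–35 bins per dimension) and as the Pearson
correlation between predicted and observed counts, inside a five-fold
training/validation/testing protocol.

A built-in simulator generates all test data: a feedforward network of leaky
integrate-and-fire neurons in which nine input cells with identical but
spatially shifted linear RFs drive a complex output cell through excitatory
depressing synapses (u = 0.9, τ_rec = 200 ms), plus a simplified two-input
variant without depression whose stimulus-response mapping is genuinely
two-dimensional.  See `docs/methods.md` for the full model and parameter
account.

## Worked example

```python
from rfctx.benchmarks import (depressing_network_config, network_benchmark,
                              simplified_network_config)

dep = network_benchmark(depressing_network_config(n_frames=50_000, seed=1),
                        seed=1)
simp = network_benchmark(simplified_network_config(n_frames=50_000, seed=2),
                         seed=1)
print(f"depressing network : context {dep['context_info']:.2f} bits, "
      f"two-filter LN {dep['ln2_info']:.2f} bits")
print(f"simplified network : context {simp['context_info']:.2f} bits, "
      f"two-filter LN {simp['ln2_info']:.2f} bits")
```

which prints (a few minutes per network on one CPU):

```
depressing network : context 0.88 bits, two-filter LN 0.47 bits
simplified network : context 1.61 bits, two-filter LN 1.89 bits
```

Each number is the bias-corrected single-spike information of that model's
held-out similarity scores, in bits per spike: how much observing the score
tells you about when the cell fires.

On the nine-input depressing network the context model describes the cell far
better: its RF marks the pooled responsive region and its CF captures the
input cells' shared template together with an opposite-sign trailing tail —
the signature of synaptic depression.  On the two-input network without
depression the ordering reverses: the mapping lives in a two-dimensional
stimulus subspace, and the two-filter LN model with its free two-dimensional
nonlinearity wins.

The same models are available from the command line:

```bash
rfctx simulate --network nine-depressing --frames 50000 --seed 1 --out data.h5
rfctx fit-context --data data.h5 --family poisson --out ctx.h5
rfctx fit-ln --data data.h5 --method stc --filters 2 --out stc.h5
rfctx compare --config run.yaml
```

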