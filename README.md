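# tdmdscreen

Screening for EBAX-1/ZSWIM8-sensitive miRNAs — candidate substrates of
target-directed miRNA degradation (TDMD) — from mutant-vs-wild-type
small-RNA sequencing, implemented end to end:

* **Counting** — miRNAs by exact 19-nt prefix match against a curated
  dictionary (pooling 3'-tailed/trimmed isomiRs under the parent miRNA,
  merging identical mature sequences), piRNAs by perfect full-length
  match, spike-ins separated out; CPM normalisation (pseudocount 1 for
  miRNAs) and a ≥ 5 CPM wild-type expression filter.
* **Differential expression** — a two-group negative-binomial Wald test
  (median-of-ratios size factors, trend-shrunk method-of-moments
  dispersion), statsmodels-style: `NBDEModel(counts).fit()` returns an
  `NBDEResults` with the per-feature table and a `summary()`.
* **BBUM calling** — a bi-beta uniform mixture over the signed p-values
  separates the upward primary effect from noise and bidirectional
  secondary effects and yields a model-based FDR; miRNAs with positive
  log2FC and FDR < 0.01 are called sensitive, each with a
  passenger-strand sanity contrast.
* **Pool fraction** — the fraction of cellular miRNA molecules degraded
  through the ligase, from raw counts scaled on the non-sensitive sums.
* **Isoform profiling** — 14 exact tail/trim isoform classes per miRNA
  with spike-in miscall calibration.
* **Target CDF analysis** — repression of predicted targets vs
  3'-UTR-length-matched controls, two-sample Kolmogorov-Smirnov test.
* **piRNA block scan** — sliding-window localisation of contiguous
  blocks of coordinately downregulated piRNAs.
* **Synthetic data** (`tdmdscreen.simkit`) — dictionaries, NB counts,
  reads, spike-ins, piRNA panels and mRNA tables with planted ground
  truth, fully seed-deterministic, so every stage is testable without
  external data.

The mixture at the core models positive- and negative-direction Wald
p-values as

    f+(p) = λ + (1−λ)[θ·a_p·p^(a_p−1) + (1−θ)·a_s·p^(a_s−1)]
    f−(p) = λ + (1−λ)·a_s·p^(a_s−1),      0 < a_p ≤ a_s < 1

with FDR(p) = [λp + (1−λ)(1−θ)p^{a_s}] / [λp + (1−λ)(θp^{a_p} + (1−θ)p^{a_s})].
See `docs/methods.md` for the full model descriptions and numerical
choices.

## Worked example

```python
from tdmdscreen import simkit, readcount, diffexpr, bbum, poolfrac

cfg = simkit.SimConfig(seed=1, n_families=300, family_sizes=(1,) * 300,
                       frac_sensitive=0.1, depth=2e6)
data = simkit.simulate_dataset(cfg)          # dictionary, spikes, truth, counts

res = diffexpr.NBDEModel(data["counts"], stage="L1").fit()
guides = [e.name for e in data["dictionary"].guides()]
gtab = res.table.loc[guides]
gtab = gtab[gtab.status == "tested"]

fit = bbum.fit_bbum(gtab, seed=1)
print(fit.summary())
calls = bbum.call_sensitive(gtab, fit, threshold=0.01)
called = set(calls.index[calls.called])
planted = set(data["truth"].sensitive_guides("L1"))
print(f"called {len(called)} sensitive miRNAs; "
      f"{len(called & planted)} of {len(planted)} planted recovered")

frac = poolfrac.degraded_fraction(data["counts"], called, "L1")
print(frac.to_string(index=False))
```

prints (seed 1):

```
BBUM mixture fit (joint, converged=True)
  features: 300 (175 positive direction)
  lam (null mass)      = 0.7780
  theta (primary share)= 0.9988
  a_p (primary shape)  = 0.0756
  a_s (secondary shape)= 0.9999
  log-likelihood       = 310.62
called 29 sensitive miRNAs; 29 of 30 planted recovered
stage replicate   scale       surplus  fraction
   L1         1 1.01985 271708.780491  0.129675
   L1         2 0.97942 245363.366325  0.123610
   L1      mean     NaN           NaN  0.126643
```

The near-flat secondary (a_s ≈ 1) is the expected appearance of a dataset
with no true bidirectional secondary effects — the non-null mass is
almost entirely the primary spike (a_p ≈ 0.08, θ ≈ 1), which carries the
planted signal: 29 of the 30 planted sensitive miRNAs are recovered with
no false calls.  Roughly 12.7% of the mutant's miRNA pool is surplus —
molecules the ligase pathway would have degraded in the wild type.

A `tdmd` CLI wraps the same stages
(`tdmd simulate | count | de | call | fraction | isoforms | targets | pirna-scan`);
run any subcommand with `--help`.

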