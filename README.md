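# txroadblock

Simulation and binned differential analysis of RNA polymerase II
elongation **roadblocks** in nascent (chromatin-associated) RNA-seq.

Catalytically dead Cas9 (dCas9) bound inside or downstream of a gene acts
as a physical roadblock for the elongating Pol II complex — but only when
the sgRNA targets the **non-template (NT) strand**; template-strand
targeting lets Pol II pass. The consequences depend on where the block
sits relative to the polyadenylation site (PAS): an intragenic block
aborts transcripts and lowers expression; a block downstream of the PAS
suppresses readthrough and shifts the termination zone upstream without
changing mRNA output; a block between two PAS shifts alternative
polyadenylation (APA) toward the proximal site.

`txroadblock` provides, as a single testable pipeline:

* a stochastic per-bp **elongation simulator** (pause peak 19 bp upstream
  of the dCas9 site, Bernoulli termination at the block, per-PAS cleavage
  commitment, geometric torpedo run-on with per-bp hazard *h*) emitting
  occupancy tracks, BED fragment libraries and transcript fates;
* **binned differential signal**: 500-bp bins over a locus, fragment
  overlap counting, median-of-ratios size factors, per-bin
  log₂((t+1)/(c+1)) fold change, and a Monte-Carlo **binomial test** —
  for each bin, k = treated reads of n = treated+control reads against
  Binomial(n, ½), p-values from 10⁶ simulated draws (exact tail sums as
  the fast/oracle mode), significance at p < 1×10⁻⁵;
* **matched negative controls**: untargeted genes within ±2,500 bp of the
  target's length and ±5 TPM of its expression, each analysed identically;
* **ratio metrics**: downstream/upstream readthrough ratio, up/down APA
  ratio and mRNA expression ratio, all control-normalised, plus a
  boundary estimator that localises the block from the significance
  pattern.

The default locus is the 86,166-bp study window chr12:104,286,383–104,372,549
(TXNRD1), which tiles into 173 bins of 500 bp (final bin 166 bp).

## Worked example

```bash
python examples/02_binned_differential_test.py
```

```
173 bins, 168 significant at p < 1e-05
roadblock placed in bin 40; estimated boundary bin 41
maximal positive log2FC in bin 40 (log2FC 2.35) — the pause peak
first bins past the boundary, log2FC: [-1.05 -1.08 -1.06 -1.07]
```

A roadblock with termination probability τ = 0.8 was simulated in bin 40.
The bin holding the stall point shows a strong **positive** log₂FC (the
Pol II pause peak piles up nascent RNA just upstream of the dCas9 site);
every bin downstream is significantly **depleted** (readthrough thinned
to 1−τ of control, here ≈ −1 in log₂ after depth renormalisation), and
the boundary estimator places the block within one bin of truth. The
other examples (`examples/0*.py`) walk through the simulator itself,
readthrough vs expression outcomes, the APA sweep and matched-control
specificity, each printing the quantities it computes.

The same analysis runs from a shell:

```bash
txroadblock scan --config examples/scan_config.yaml --out scan_out
```

writing coverage bedGraphs, bin-track TSVs, the per-bin test table, the
masked heatmap matrix and a JSON summary (byte-identical on re-run with
the same config and seed). Real data enter through the same interfaces:
BED fragment intervals (`txroadblock bin`) or per-bin count TSVs
(`txroadblock test`).

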