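# Methods

## The elongation model

The simulator is a discrete per-bp model of Pol II elongation complexes
(ECs) over a single gene locus. There is no explicit time axis:
occupancy is dwell weight, because the downstream analysis consumes
relative coverage (chromatin RNA-seq signal tracks Pol II density), not
kinetics. Each of the `n_ec` ECs initiates at the TSS and deposits one
unit of weight per bp traversed. Events along the locus, in genomic
order:

* **Roadblock (NT orientation only).** The EC stalls `pause_offset` bp
  upstream of the dCas9-binding site — the distance from the polymerase
  active centre to its front edge — and deposits an extra
  `pause_dwell − 1` weight units per bp over the pause window
  `[stall − pause_width, stall)`, i.e. occupancy in the window is
  `pause_dwell` times baseline. It then terminates with probability τ
  (`term_prob`) or resumes. Template-strand (T) targeting is implemented
  as pure pass-through whatever τ and dwell are configured (a warning is
  emitted if they are set): dCas9 acts as a one-way valve and obstructs
  only ECs arriving from the PAM-distal side.
* **PAS crossing.** At PAS *k* an uncommitted EC commits to cleavage
  there with probability `pas_commit[k]`; the terminal PAS always
  commits. After commitment a per-bp termination hazard *h* applies
  (torpedo-mechanism stand-in), so run-on distance is geometric with
  mean 1/h.
* **Locus end.** Traversal is truncated; uncommitted runoff ECs are
  tallied `premature_no_pas`.

Fates partition the initiated ECs exactly (`terminated_at_block`,
`terminated_in_zone_at_pas_k`, `premature_no_pas`); conservation is
asserted in the constructor. Only PAS-committed ECs yield mRNA —
roadblock-aborted transcripts upstream of every PAS are degraded. With
`inter_pas_rescue` on, blocked ECs that already crossed a skipped
proximal PAS are polyadenylated there, which yields the closed-form
proximal usage c + (1−c)τ for an inter-PAS block and is the mechanism of
the simulated APA shift.

Fragment libraries are sampled with start positions multinomial in the
density and fixed length (`frag_len`, default 150 bp), truncated at the
locus end. Exactly `n_fragments` fragments are drawn whatever the total
occupancy, emulating libraries sequenced to a fixed depth; relative
redistribution of signal (upstream enrichment when a block removes
downstream mass) is therefore part of the simulated signal, as it is in
real depth-normalised libraries. Randomness uses labeled substreams of
one integer seed (fates vs fragments), so requesting more fragments
never perturbs fates.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `pause_offset` | 19 | bp | bacterial RNAP front-edge gap at a dCas9 collision, the only quantitative pause geometry on record |
| `pause_width` | 50 | bp | sharp, sub-bin pause footprint; keeps the peak within one 500-bp bin |
| `pause_dwell` | 20 | — | phenomenological; raises the pause bin ~3× so it is unambiguous at library scale |
| `term_prob` τ | scenario | — | free parameter of every experiment; no measured value exists for dCas9 |
| `term_hazard` h | 5×10⁻⁴ | /bp | mean post-PAS run-on 1/h = 2 kb with a multi-kb tail, a wide native termination zone a few kb past the PAS |
| `pas_commit` | (…, 1.0) | — | terminal PAS always commits; proximal commitment is the APA lever |
| `n_ec`, `n_fragments` | 10⁶, 10⁶ | — | one nascent transcript ≈ one fragment; at this scale counting noise dominates EC-fate noise, which the conditional binomial null assumes |
| `frag_len` | 150 | bp | typical sonicated library insert |

The pause dwell and termination probability are **phenomenological**: no
quantitative dCas9 dwell or termination probability has been measured,
so these defaults are chosen to reproduce the qualitative roadblock
signatures (single-bin pause peak, lost native termination zone) and are
exposed in the config.

The default locus is chr12:104,286,383–104,372,549 (86,166 bp; 173 bins
of 500 bp, last bin 166 bp). The terminal PAS is placed 10 kb before the
locus end — a phenomenological placement leaving the termination zone
inside the analysed window — and the TSS at the locus start; neither is
an annotation lookup.

## The binned differential test

Fragments are counted on adjacent 500-bp bins anchored at the locus
start; a fragment increments **every** bin it overlaps by ≥ 1 bp (the
per-bin overlap convention; whether boundary-straddling fragments should
instead count once is not decidable from the procedure being mirrored,
so the convention is documented and oracle-tested). The final partial
bin is kept and not length-normalised.

Size factors are the median-of-ratios estimator: reference per gene =
geometric mean across samples, genes with any zero dropped via the log
convention; a sample's factor is the plain median (mean of the two
middle values for even counts, for cross-platform determinism) of its
count/reference ratios. Factors are estimated on gene-level counts and
applied to bin tracks. Note the estimator is equivariant only in factor
*ratios*: scaling one of S samples by c rescales the reference by
c^(1/S), so the individual factors move as the worked example
(identical two-sample matrix, one column ×4 → factors 0.5 and 2.0)
shows.

Per bin, the normalised counts are rounded half-to-even (the null is a
discrete binomial; the mirrored procedure does not state its rounding)
into k = treated and n = treated + control, and tested against
Binomial(n, ½). The Monte-Carlo mode draws `n_sim = 10⁶` null samples
and reports the add-one estimate (1 + #{|Sᵢ − n/2| ≥ |k − n/2|})/(N+1),
which is never exactly zero; the exact mode computes tail sums
(`scipy.stats.binom`), two-sided as the doubled smaller tail capped at
1. Two-sided is the default — the heatmap reports both elevated (pause)
and depleted (readthrough-loss) bins — with one-sided options exposed;
the sidedness of the original procedure is not recoverable. `auto`
switches to exact above n = 10⁵, where the MC estimator adds nothing.
Significance is p < 1×10⁻⁵ per bin with **no** multiple-testing
correction, mirroring the fixed threshold; the implied family-wise
false-positive expectation is ~173 × 10⁻⁵ ≈ 0.002 per locus, which the
null-calibration study measures directly.

The roadblock boundary estimator — the most upstream significantly
depleted bin whose upstream neighbour is not significantly depleted — is
this package's operationalisation of what is otherwise done by
inspection; with the default geometry the pause bin sits immediately
upstream of the boundary, so the estimate lands one bin downstream of
the block bin (within the ±1-bin tolerance used throughout).

## Checkpoints and ratio metrics

US/DS (readthrough) and up/down (APA) signals are fragment counts over
declared intervals — the in-silico analogue of qPCR amplicons. Default
study geometry places 1-kb checkpoints ≥ 200 bp clear of the pause
window so 150-bp fragment smearing cannot mix pause and readthrough
signal; with that separation the control-normalised DS/US ratio is an
unbiased estimator of 1−τ (local profile shapes cancel in the ratio of
ratios). The APA "down" checkpoint starts 100 bp downstream of the
dCas9 site: at τ = 1 the region's true density is zero and the signal
rests on the fragment-length bleed floor from the pause window, keeping
the ratio finite at the degenerate endpoint of the sweep. Because the
pause peak bleeds into "down", the normalised APA ratio at τ = 0 sits
below 1; the claim made (and tested) is monotonicity in τ plus the
closed-form proximal usage, not the τ = 0 intercept. Checkpoint
positions are fully user-declared in configs, since amplicon placement
is gene-specific.

## Study conditions and what they show

The seeded studies (`txroadblock.studies`, also driven by
`scripts/acceptance.py`) run at the default scale — 10⁶ ECs, 10⁶
fragments, the 173-bin default locus, 20 seeds per multi-seed study;
exact tails as the analysis mode, with the MC estimator validated
against exact tails on 100 random (k, n), k drawn from the
Binomial(n, ½) null so p-values span (0, 1] as real null bins do. The
MC/exact agreement bound allows the add-one floor 2/(N+1) on top of
4 MC standard errors, which matters only when the exact p is below
~1/N.

The generator emulates the statistical structure the analysis assumes —
Poisson-like counting noise on a fixed grid, depth renormalisation,
localized pause excess, downstream thinning — and deliberately not:
sequence context (no PAM search or sgRNA design), strand-split coverage,
replicate-level biological variability, mappability or GC bias, ChIP or
nucleotide-resolution nascent-RNA readouts, chromatin-mark spreading.
Passing studies therefore show the pipeline is calibrated and recovers
known effects under its own noise model; they do not certify behaviour
under real-library artefacts.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere internally and in
  BED/bedGraph; browser-style strings are 1-based inclusive and
  converted on read.
* log₂ fold changes use pseudocount 1.0 on normalised counts, so empty
  bins give 0 and all values are finite.
* n = 0 bins return p = 1 (no information), never significant.
* Zero-coverage genes in the control panel are "untestable", not zero
  significant bins; zero checkpoint signals raise an error naming the
  checkpoint rather than returning infinities.
* The fragment sampler refuses an all-zero density; the size-factor
  estimator refuses matrices with no all-nonzero gene, with a fallback
  to library-size factors (logged) only inside the control panel where
  a partial annotation is routine.
* Argmax ties (flat pause window) resolve to the lowest coordinate;
  boundary-estimator ties resolve to the smallest bin index.
* Seeds: one integer per run; labeled substreams (CRC-mixed, < 2³¹)
  isolate stages and study arms.

## Known limitations

Single-locus, single-strand analysis (strand splitting belongs to the
alignment stage); no replicate model or dispersion estimation — the
binomial null is conditional on the two libraries compared, which is
exactly the mirrored procedure but anticonservative under biological
replication; the pause dwell/termination parameters are phenomenological
dials, not measurements; TPM for control matching is computed from the
untreated library (matching should not be distorted by the
perturbation — the choice the original matching leaves open); the
annotation universe for candidate controls is whatever table the user
supplies.
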