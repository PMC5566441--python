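# Methods

## Measurement model

A droplet dPCR well partitions one reaction into n droplets (n ≈ 10,000 –
25,000 accepted). If N template molecules are distributed uniformly at
random, per-droplet occupancy is Poisson with mean λ = N/n and the fraction
of negative droplets estimates e^(−λ). The concentration estimator is

    λ̂ = −ln(neg/total),      var(λ̂) ≈ (1 − p̂)/(total · p̂),  p̂ = neg/total,

the delta-method variance of the log of a binomial proportion. Copies per
reaction is λ̂·n (accepted droplets only; unread emulsion volume is outside
the model, consistent with how droplet readers report). Copies per µl of
original sample divides by the effective sample volume of the dilution
chain — the product of the sample input volume and every aliquot/final
volume fraction along the protocol. The default chain (0.5 µl sample →
5 µl pre-anneal → 10 µl RT → 95 µl dilution → 9.5 µl into a 20 µl reaction)
gives 0.05 µl of original sample per reaction.

Confidence intervals are normal on λ̂; when either droplet class has fewer
than 30 members the interval switches to exact Clopper–Pearson bounds on the
negative fraction mapped through −ln, which keeps the lower bound at 0 for
all-negative wells and remains defined in deep-subsampling regimes.

### Paired RT⁺/RT⁻ statistics

Transcripts per gene t/g = (N⁺ − N⁻)/N⁻ is computed on any common unit
(copies/reaction or copies/µl; the ratio cancels volume). Uncertainty is
first-order propagation treating the two aliquots as independent:
var(t/g) = var(N⁺)/N⁻² + N⁺²·var(N⁻)/N⁻⁴. Negative t/g values are reported
as-is; `detected` is False when the CI spans zero, which is how a
non-transcribed gene presents. Copies per genome is the analogous ratio of
two RT⁻ (DNA-only) estimates against a single-copy nuclear reference;
transcripts per genome is the product of the two. Reverse-transcription
efficiency is treated as 1 in estimation (no correction applied); the
simulator can set ε < 1 to quantify the resulting downward bias in t/g.

Replicate-level results are summarized as mean ± SEM (sample SD/√n) and
compared by one-way ANOVA with Bonferroni-adjusted pairwise t tests
(raw p × number of pairs, capped at 1).

## Droplet classification

The automatic threshold is an Otsu split: maximize between-class variance on
a 256-bin histogram of the well's amplitudes, threshold at the best bin
edge, positives strictly above (droplets exactly at the threshold are
negative). A bimodality guard rejects splits whose class means are closer
than 4 pooled within-class standard deviations; such wells — no-template
controls, constant or unimodal amplitude distributions — are flagged and
classified all-negative rather than split arbitrarily. The guard constant
trades sensitivity in extremely sparse wells (a handful of positives among
tens of thousands of negatives can be absorbed into the flagged case)
against never bisecting a pure negative cloud; manual per-target thresholds
are available in the run config for such wells.

## QC flags

* `SATURATED`: no negative droplets, or copies/reaction above the dynamic
  range ceiling (default 10⁵ copies/reaction).
* `TOO_FEW_DROPLETS`: accepted droplets below the floor (default 10,000).
* `HIGH_SUBSAMPLING_ERROR`: relative CI half-width above the cap (default
  25%).
* `NTC_CONTAMINATION`: the target's no-template control shows more positive
  droplets than the ceiling (default 5).

All four thresholds are run-config constants.

## Generative simulator

The simulator replaces the wet lab for testing and power analysis. For one
sample/target with genome density g (genomes/µl), gene copy number c per
genome, transcription t per gene copy, and effective sample volume v:

* amplifiable DNA fragments/reaction ~ Poisson(g·v·c / f), where f is
  `copies_per_fragment` — tandem copies left on one undigested restriction
  fragment (f = 1 models complete digestion). Co-partitioned copies produce
  one positive droplet, which is exactly the downward copy-number bias that
  motivates digesting before partitioning; `linkage_bias_experiment`
  reproduces the bias curve, collapsing to ~1 fragment/genome at full
  linkage.
* transcripts/reaction ~ Poisson(g·v·c·t); cDNA ~ Binomial(transcripts, ε)
  with RT efficiency ε, present only in the RT⁺ aliquot. The RT⁻ aliquot
  never contains cDNA; single-stranded gene DNA is not modeled (RT⁻
  measures double-stranded gene copies).
* molecules are assigned to droplets by a multinomial throw — equivalent to
  iid Poisson occupancy, so the estimator's model is exactly the simulator's
  partition law.
* amplitudes are Gaussian, defaults μ_neg 2000, μ_pos 9000, σ 300 (fixture
  constants, not instrument claims). "Rain" redraws a fraction of *occupied*
  droplets uniformly between the modes: physically, rain is delayed or
  partial amplification in droplets that do contain template. Drawing rain
  from all droplets instead would inject false positives worth ~r/2 of the
  total, a λ bias exceeding 10% at low occupancy — incompatible with the
  sub-percent estimator bias the clean model must exhibit. Rain default is
  1% of occupied droplets.
* nuclease treatments are multiplicative survival fractions on the RNA and
  DNA pools (RNase: 0 RNA, 81% DNA; dsDNase: 95% RNA, 10% DNA), enabling
  in-silico validation experiments of the RT⁺/RT⁻ interpretation.
* scenarios whose expected occupancy exceeds 50 copies/droplet are refused
  as unphysical.

Defaults emulate a whole-brain lysate measured for a single-copy nuclear
gene: 12,160 genomes/µl × 0.05 µl → ~608 gene copies per 20,000-droplet
reaction, 1.95 transcripts per gene.

The tissue-panel generator carries per-tissue ground truth for a single-copy
gene (t/g 2.03 brain, 0 heart, 0.25 liver and muscle), a 107-copy ribosomal
gene (t/g 349/1496/27/6), and mtDNA (1096/2302/1759/1774 copies per genome;
per-strand transcription H 0.55/0.58/1.70/0.56 and L 0.37/0.37/0.44/0.36
transcripts per mtDNA copy), with heavy- and light-strand targets simulated
separately and combined. Each target receives an automatic extra dilution
bringing its expected RT⁺ occupancy to λ ≈ 3.5 — high in the dynamic range
deliberately, so that strongly transcribed targets (ribosomal t/g ≈ 1500)
retain a countable RT⁻ signal in the same chain; this mirrors the bench
practice of adjusting the analyzed sample volume per target, and the
per-target chains are returned so concentrations normalize back to the
sample scale.

### What the simulator does not emulate

Per-droplet volume variation, PCR amplification kinetics and inhibitors,
primer thermodynamics and nonspecific priming, and instrument-specific
amplitude structure are all outside the model. Passing recovery tests
therefore demonstrates the correctness of the statistical pipeline under
ideal partitioning, not robustness to chemistry-level artifacts; conversely
the rain and linkage knobs bound two artifact classes that do matter for
the statistics.

## Numerical choices

* Ties at the threshold are negative (strict `>` for positive).
* Thresholding operates on histograms, so it is invariant to droplet order.
* The exact-CI switch at 30 counts per class follows the usual normal
  approximation rule of thumb.
* Merged replicate wells pool raw counts (sum of positives/negatives),
  retaining per-well threshold provenance; pooling agrees with
  precision-weighted averaging exactly for identical wells and to first
  order otherwise.
* Report tables round t/g to 2 decimals and per-genome counts and
  percentages to integers; machine-readable outputs keep full precision.
  All output files use fixed number formatting, so identical inputs and
  seeds give byte-identical outputs.
* Problem sizes in the test suite (well counts per Monte-Carlo check,
  replicate numbers) are chosen to give stable pass/fail margins at a few
  seconds per check; the statistical criteria they verify (bias, coverage,
  recovery rates) are sample-size-calibrated accordingly.

## Known limitations

* The t/g denominator is a measured quantity; at very low RT⁻ occupancy the
  ratio's delta-method CI degrades. The panel generator's λ ≈ 3.5 working
  point keeps denominators ≥ ~45 copies, but real plates with extreme t/g
  may need a dedicated less-diluted RT⁻ well.
* At high occupancy the Otsu midpoint threshold loses roughly half of the
  rain droplets to the negative class, biasing λ̂ down by ~r/2 relative
  among positives (≈ −2% at λ 2–3.5 with 1% rain). Ratio statistics cancel
  most of it, but absolute concentrations of rainy high-λ wells inherit it.
* The method quantifies total RNA for the amplicon — primary plus processed
  forms — and cannot resolve isoforms.
* One fluorescence channel is assumed (intercalating-dye chemistry); the
  file schema reserves a channel column for duplex assays but the classifier
  is 1-D.
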