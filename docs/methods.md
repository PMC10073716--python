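# Methods

## Scope and data model

The pipeline starts at a PSM (peptide-spectrum match) table — one row per
identified spectrum with a peptide, a protein accession, the peptide's
1-based start position, zero or more mass shifts (`offset:delta`, 0-based
peptide offsets, `-1` for the peptide N-terminus), a q-value, a pool label,
and the eight iTRAQ 8-plex reporter intensities (channels 113–119, 121).
Everything upstream (spectra, database search, PTM localization) is out of
scope; everything downstream (site annotation, quantification,
stoichiometry, clinical statistics, sequence context) is deterministic given
the table and the configuration.

The default reporter design maps channels 113, 114, 119 to the
normozoospermic (NZ) group and 115, 116, 117, 118, 121 to the
non-normozoospermic (nonNZ) group — three NZ and five nonNZ pools.  Pool
labels (`NZ1` … `nonNZ5`) follow channel order.

## Mass-shift classification

Reference monoisotopic deltas, from atomic-mass arithmetic:

* citrulline / deamidation: O − N − H = 15.994915 − 14.003074 − 1.007825
  = **+0.984016 Da** (carried as 0.98402);
* homocitrulline / carbamylation: H + C + N + O = **+43.005814 Da**
  (carried as 43.00581).

A shift is assigned iff it is within an absolute tolerance (default
**0.01 Da**) of a reference *and* the residue/position rule matches: Cit on
R, deamidation on N/Q (isobaric with Cit; residue identity is the only
discriminator available at the table level), hCit on K, N-terminal
carbamylation at offset −1.  Everything else is `Other` — never an error.
The 0.01 Da default is a class-assignment tolerance, not a search
tolerance: it separates the two references by three orders of magnitude
while tolerating rounding in exported tables.  Shrinking the tolerance can
only move assignments toward `Other` (monotonicity, property-tested).

Sites aggregate PSM-level calls per (accession, position); the site class
is the modal class over supporting PSMs, ties broken by higher total
supporting intensity, then lexicographic class name — an arbitrary but
deterministic rule.  Cit calls on a peptide's C-terminal arginine are
flagged (trypsin does not cleave after citrullinated Arg) unless the
peptide ends at the protein C-terminus; flagged sites are reported, not
removed.  The identification filter keeps PSMs with q strictly below 0.01.

## Quantification

Cumulative burden uses spectral counting by default (each PSM is one count,
assigned to its pool and thereby its group); summed reporter intensity over
the group's channels is carried alongside, and a nonNZ − NZ difference row
is emitted.  Protein quantification sums reporter intensities per protein
and channel, normalizes each channel to unit total (per-channel relative
intensities; the data-scale-free target makes results strictly invariant to
rescaling any single channel, which a grand-mean target would not be), and
tests NZ vs nonNZ channel values per protein with an equal-variance pooled
Student *t*.  A zero pooled variance is floored at machine epsilon times
the squared grand mean, so a genuine mean difference under degenerate noise
yields an extreme finite statistic.  No multiple-testing correction is
applied by default (significance is a plain p ≤ 0.05); Benjamini–Hochberg
is available as an option.  Median-ratio normalization (per-protein
geometric-mean reference) is offered as an alternative.

## Site stoichiometry and the χ² comparison

A site's per-group stoichiometry is `100 · I_mod / (I_mod + I_unmod)`,
where the sums run over the group's channels and over PSMs whose peptide
covers the site position with (resp. without) a ureido modification at that
position; the percent is scale-invariant and reported to two decimals.
Groups are compared with a Pearson χ² (1 df, no continuity correction) on
the 2×2 table of intensities **rounded to integer pseudo-counts**.  This
convention matters: the test treats intensity units as counts, so its
p-values are calibrated only when the intensity scale is about one unit per
PSM.  The synthetic generator emits reporter intensities on exactly that
scale, and a raw spectral-count variant (`estimator="counts"`), for which
the test is exactly count-based, is provided.  The direction flag compares
the 2-decimal percents (↑ iff patients exceed controls, `=` only on an
exact tie); a zero margin skips the test but keeps the direction.

## Clinical statistics

All tests are two-sided.  Group comparisons use the pooled Student *t* with
per-group mean ± SD; missing values are deleted pairwise and the n used is
always reported.  Correlations are Pearson or Spearman (average ranks on
ties) with r undefined on zero variance.  Confound screening tests each
lifestyle flag (smoking, alcohol, toxicology) against each continuous
clinical variable (pooled *t*; degenerate flags skipped) and correlates age
with every clinical variable that differs significantly between groups, and
with the modification burden when one is supplied, all at p < 0.05.

In the end-to-end pipeline the hCit burden exists only per channel pool, so
the burden-vs-clinical correlation is computed across the 8 pools with each
pool carrying its group's mean clinical value.  With only two distinct
clinical values this is effectively a point-biserial correlation with the
same magnitude for every variable — an honest limitation of pooled designs,
stated here so it is not mistaken for a subject-level estimate.
Subject-level correlations are available whenever per-subject burden is
known (as with the simulator's ground truth).

## Sequence context

Cit windows are the ±10-residue context of the modified arginine, truncated
at protein termini.  Windows are stacked center-anchored with no gaps —
they are fixed-length and pre-anchored by construction, so a general
multiple aligner would add nothing but nondeterminism — padded with `-`,
which scores zero and is excluded from consensus denominators (truncated
windows must not dilute agreement).  Columns are scored as BLOSUM62
sum-of-pairs (matrix from biopython).  Consensus columns report the modal
residue (lexicographic tie-break), percent agreement, and shading at
strictly >60 % (mid) and >40 % (light); non-conserved columns are marked
`+`.  Conservation uses a Jalview/AMAS-style 0–11 score: one point per
physicochemical property class (hydrophobic, polar, small, proline,
aliphatic, aromatic, positive, negative, charged, tiny, buried — the class
table ships in `motif_analysis.PROPERTY_CLASSES`) whose membership is
uniform down the column, capped at 10 for non-identical columns, with 11
reserved for full identity.  "No consensus at all" is interpreted as no
non-center column exceeding 40 % agreement (`has_consensus`).  Domain
overlap is closed-interval containment on 1-based coordinates.
Functional-category percentages round to the nearest integer, halves away
from zero; the unrounded percentages sum to exactly 100.

## Synthetic data generator

The generator defines the study conditions; it is a first-class, tested
module, not a fixture.

* **Design**: 12 NZ / 14 nonNZ subjects; 3 + 5 channel pools (the channel
  enumeration above).
* **PSM emission**: for each roster peptide and pool, a Poisson number of
  PSMs (default mean 12 per peptide per pool, scaled by protein abundance).
  Each PSM covering a ground-truth site is modified with probability equal
  to that group's true stoichiometry — Bernoulli per PSM, so stoichiometry
  is binomial at the PSM level, the same sampling unit the intensity-ratio
  estimator uses.  Reporter intensity is lognormal (σ = 0.3) around one
  unit and is emitted in the PSM's own pool channel, keeping intensity
  totals and spectral counts on a common scale (see the pseudo-count note
  above).  Confounds: deamidation of a random N/Q at rate 0.05 per PSM,
  N-terminal carbamylation at rate 0.02; 3 % of PSMs receive q-values above
  the 1 % identification cut.
* **Roster**: eight citrullinated proteins with group-specific site
  stoichiometries spanning the 15–77 % range (controls slightly above
  patients except one site with the opposite direction), hCit carrier sites
  elevated roughly threefold in the nonNZ group, and EV-marker background
  proteins with exosome markers more abundant than microvesicle markers.
  Sequences are random over the 19 non-Arg residues with R/K planted at
  site positions.
* **Clinical covariates**: latent per-subject hCit burden (group means
  1.0 / 1.8, SD 0.2); morphology and motility are linear in the
  cohort-standardized burden with slope r = −0.6 (the configured
  correlation) plus independent Gaussian noise, so the cohort-level Pearson
  correlation equals the target and the NZ–nonNZ difference in those two
  variables emerges through the burden gap.  Applying an additional
  explicit group shift on top of the correlation construction would
  overshoot the configured r (the group-mean alignment adds to the
  within-group correlation), which is why vitality (75 / 58 ± 9 %) and
  count (80 / 35 ± 20 ×10⁶/ml) carry explicit shifts while morphology
  (base 6 ± 2.5 %) and motility (base 40 ± 12 %) do not.  Age is
  N(35, 5²) clipped to [22, 50] and independent of everything else;
  lifestyle flags are Bernoulli (0.30 / 0.40 / 0.08).  Values are clipped
  to their physical ranges; clipping is rare at the default settings.
* **Ground truth** (site stoichiometries, expected group hCit counts,
  subject burdens, clinical means) is returned and written to
  `manifest.yaml`.  Everything is deterministic given the seed; identical
  seeds give byte-identical bundles.

What the generator does **not** emulate: spectrum-level structure
(fragmentation, interference, isotope impurity of reporter channels),
retention time, shared peptides between proteins, realistic tryptic
digestion (peptides are fixed-length windows), channel-level batch effects,
and subject-to-pool mixing (pools are the sampling unit for PSMs; subjects
appear only in the clinical table).  Passing recovery tests therefore show
that the estimators are correct under the stated sampling model, not that
they are robust to the full messiness of real reporter data.

## Problem sizes used in the tests

Worked-example stoichiometries use the constructed intensity pairs
directly.  The χ² oracle check runs 1,000 random 2×2 tables against an
independent Σ(O−E)²/E implementation at 1e-9.  Null calibration pools 250
independent equal-stoichiometry sites at ~320 covering PSMs each and
expects a 5 ± 3 % rejection rate (the lognormal intensity noise inflates
the intensity-based χ² by about e^{σ²} ≈ 9 %, which stays within the
band at σ = 0.3).  Parameter recovery averages 20 seeds at ≥2,000 covering
PSMs per seed (binomial SE ≈ 1 point per seed) and 20 cohorts of n = 26
for the clinical correlation (per-cohort SE of r ≈ 0.13).  These sizes are
the package's own test conditions and run on one CPU in well under a
minute each.

## Known limitations

* Cit vs deamidation relies entirely on residue identity; a mislocalized
  search-engine assignment propagates.  No localization scores are carried.
* χ² on intensity pseudo-counts is anticonservative when intensities are
  much larger than one unit per PSM; rescale inputs or use the counts
  estimator.
* Protein inference is out of scope: each PSM carries a single accession by
  contract.
* Pool-level clinical correlations (n = 8, two distinct clinical values)
  have very limited power and identical magnitude across variables; they
  are reported for completeness, not inference.
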