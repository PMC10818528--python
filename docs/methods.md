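# Methods

## Model and assumptions

The read-across model assumes that, within a category of chemicals
sharing a specific mode of action (here AChE inhibition), acute aquatic
toxicity is driven jointly by hydrophobicity (log K<sub>ow</sub>) and a
species-specific sensitivity that is a property of the *species*, not of
the individual chemical. Under that assumption the ratio of two
chemicals' LC50s for the same species — the species sensitivity ratio,
SSR — is approximately constant across species, and its geometric mean
over donor species (the species sensitivity factor, SSF) transfers from
the taxa where both chemicals are tested to taxa where only the source
chemical is.

The prediction is multiplicative, `predicted = SSF × LC50_source`, and
every statistic downstream works on log-transformed values, where the
model is additive. Because the target chemical is defined as the member
with the higher log K<sub>ow</sub>, an admissible SSR is ≤ 1; shared
species with SSR > 1 contradict the premise and are excluded from
donation (but still receive predictions, since they have source data).
SSR exactly 1 is neutral evidence and is retained.

## Scenarios and donor enumeration

* **Case I** — matched species in at least three prediction taxa. For a
  candidate species, one matched species is drawn from *each* other
  prediction taxon and all cross-combinations are enumerated; each
  combination's SSF is the geometric mean of its SSRs. The number of
  predictions per candidate is therefore the product of the other taxa's
  matched counts. This enumeration is what reproduces the published
  worked-example counts (12 = 4 × 3, 8 = 2 × 4, 3 = 3 × 1).
* **Case II** — exactly two matched taxa. The single other matched taxon
  donates. The default pools all its matched species into one SSF; the
  alternative `donor_selection="closest"` uses only the donor whose
  source-chemical LC50 is nearest the candidate's in log space. When the
  candidate's own taxon is not one of the two matched taxa, the matched
  taxon with more species is used (ties broken by the canonical taxon
  order).
* Fewer than two matched taxa: the pair is ineligible.

Prediction taxa default to fish, crustaceans and insects; amphibians are
carried by the data model and can be enabled per run. The published
summaries never include amphibian rows, which motivates the default.

## Classification and row decisions

A prediction below the known LC50 overestimates toxicity
(conservative); above, it underestimates. Exact equality — within
relative tolerance 1e−12, the regime only reached on noise-free
synthetic data — is a tie and counts toward neither direction. A row
(pair × taxon × species) is decided by strict majority of over vs under;
equal counts give "nd" (not determined). Predictions above the source
chemical's own LC50 for the species remain "under" but carry a
`beyond_source` flag, since they fall outside the interval bracketed by
the two chemicals.

## Agreement statistics

With residuals r<sub>j</sub> = E<sub>j</sub> − A on log-transformed
values:

* bias = mean(r); precision = sample SD of r (divisor n − 1);
  accuracy = mean |r| (MAE). MAE ≥ |bias| always (triangle inequality) —
  the test suite enforces this identity on random residual sets.
* relative bias = (e<sup>bias</sup> − 1) × 100%. The exponential is
  natural even though the default log transform is base 10; the two
  conventions are deliberately independent (`log_base` is configurable)
  because the reference formulation of the percent back-transform is
  written with `exp`. Published summary panels are reproduced within
  ±0.7 percentage points under exactly this reading.
* Bland–Altman: mean difference and limits mean ± 1.96 SD, differences
  oriented predicted − known, x-coordinates (E<sub>j</sub> + A)/2.
  A `mean_offset = |mean(E) − mean(A)|` field is reported alongside; it
  equals |bias| identically and exists to make grouped panels
  self-explanatory.
* Pearson's r via the standard product-moment formula (requires n ≥ 3
  and nonzero variance).
* The Anderson–Darling check (5% level, n ≥ 8; inconclusive below)
  annotates whether the log transform achieved approximate normality; it
  never gates any computation.

Known internal tension in published panels of this kind: a group MAE can
be printed smaller than |bias|, which is arithmetically impossible under
the MAE definition, and a panel bias can differ from the Bland–Altman
mean difference although both are means of E<sub>j</sub> − A. This
package computes each statistic from its own definition and makes no
attempt to reproduce such inconsistent pairs; the rounding-consistency
tests only assert relationships that are arithmetically forced.

## Data handling

* Canonical concentration unit is µg/L; mg/L inputs are converted by the
  exact factor 1000 at load time.
* Exposure durations 24/48/96 h are pooled as one acute endpoint by
  default (restrictable per run).
* Replicates per (chemical, species) are collapsed by geometric mean for
  any replicate count — the mean is the identity at n = 1, so no
  minimum-count branch exists.
* The water-solubility filter keeps records with LC50 strictly below the
  chemical's solubility. It is on by default but switchable, because
  published range summaries for several category members exceed their
  solubility limits; reproducing those summaries requires the filter
  off, and the worked-example reconstruction runs with it off for the
  same reason.
* The log K<sub>ow</sub> ≤ 5 category cutoff is inclusive (the packaged
  category's maximum is 4.96, so either reading admits it); a strict
  mode is available. Verhaar classes are input data, never computed.

## Synthetic generator

`toxra.simulate` draws
log10 LC50(c, s, k) = α − β·logKow<sub>c</sub> + taxon offset +
species effect + interaction + replicate noise, all effects Gaussian on
the log scale from one seeded generator. Defaults: 25 chemicals spanning
log K<sub>ow</sub> −0.85…4.96, three taxa × 8 species × 3 replicates,
α = 4.0 log10 µg/L (10 mg/L for a reference fish at log K<sub>ow</sub> 0),
β = 0.8 decades per K<sub>ow</sub> unit (a typical baseline-toxicity
slope), taxon offsets fish 0 / crustacean −1 / insect −0.5 / amphibian +1
(crustaceans most sensitive, amphibians least), species SD 0.6,
interaction SD 0.2, replicate SD 0.3 decades. A `dropout_prob` removes
(chemical, species) cells to create realistic Case II sparsity.

Because species and taxon effects cancel in every ratio, the model has a
closed-form truth SSF = 10^(−β·Δlog K<sub>ow</sub>) when the
chemical × species interaction variance is zero. Two consequences anchor
the test suite:

* **Exactness regime** — with interaction and replicate SDs both zero,
  the full pipeline reproduces every held-out LC50 exactly: all
  residuals 0, all classifications tie, r = 1.
* **Consistency** — with replicate noise only, per-pair mean log SSFs
  concentrate on the closed form as species count grows.

What the generator does *not* emulate: inter-laboratory heterogeneity,
censored or qualifier values ("greater than" LC50s), test-condition
covariates, taxonomic structure finer than the four taxa, and
non-lognormal error. Passing tests therefore demonstrate correctness of
the computation and its statistical behaviour under the stated model,
not predictive performance on real ECOTOX extracts.

## Worked-example reconstruction

Published evaluations of this method tabulate, per pair × taxon row, the
matched-species counts, an exemplar species' known LC50 and the min/max
predicted LC50 — not the underlying records. `toxra.examples` inverts
those anchors: per-taxon donor log-ratio spreads are obtained from the
printed max/min prediction ratios by solving the small linear system the
combination rule implies, donors are spread evenly over [−w, 0], the
exemplar's own ratio is pinned by its printed known value (occupying a
matched slot when ≤ 1, becoming an excluded extra species otherwise),
and exemplar source concentrations are refined by a short fixed-point
iteration since the taxa anchor one another. Slot assignments are frozen
after the first pass so counts cannot oscillate. All reconstructed
species are labelled `synthetic_*`.

The reconstruction is validated by re-running the *actual* pipeline on
the reconstructed records: matched counts, prediction counts and the
over/under verdicts of the anchored rows — including a non-trivial 5/7
split — come out as published. One crustacean row whose printed anchors
are not mutually consistent with its neighbours is reconstructed but not
asserted.

## Numerical choices and limitations

* Geometric means are computed as exp(mean(log)), with a clamp into
  [min, max] guarding the n = 1 rounding corner.
* Pair enumeration requires strictly increasing log K<sub>ow</sub>;
  exact ties produce no pair in either direction.
* Artifacts are byte-stable: pairs sorted by source then target CAS,
  predictions by taxon, species and donor key; the run manifest records
  input SHA-256 hashes and the full configuration.
* Problem sizes in the test and acceptance runs (≤ 6 chemicals, ≤ 4
  species per taxon for the noisy runs) are chosen to exercise every
  code path at interactive speed; the pipeline itself is O(pairs ×
  species × donor combinations) and handles the full 25-chemical
  category unchanged.
* No uncertainty intervals accompany predictions, chronic endpoints and
  assessment-factor derivation are out of scope, and the Verhaar
  classification and GHS hazard categories are carried as data only.
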