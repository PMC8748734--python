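# Methods

This note documents the models, conventions and numerical choices behind
`subshelf`, in the order data flows through the package.

## Synthetic communities (`subshelf.simulate`)

The generator emulates the downstream view of a deep, dark marine microbial
community sampled at several depths with replicates.

**Community model.** Genome relative abundances are log-normal
(μ = 0, σ = 1.5 by default) renormalized to sum to 1 — the standard neutral
choice for microbial rank-abundance curves; nothing downstream depends on
this family beyond producing realistic skew. Each genome carries exactly
one copy of each of 14 universal single-copy ribosomal marker families
(labelled RplB…RpsS with typical gene lengths of 260–830 bp; the labels are
package conventions for "the 14 universal single-copy markers").
Metabolic families are carried Bernoulli(prevalence) with a configurable
copy number and length; defaults plant a nitrification/carbon-fixation/
respiration panel at prevalences from 0.02 (PsbA) to 0.95 (AtpA).
Transcriptional activity multipliers are log-normal (σ = 1 by default).

**Read→gene hits.** Reads land on genes with probability proportional to
abundance × copy number × gene length (multinomial). By default 40% of the
library remains unmapped — echoing the ~60% read-assignment rates typical
of such surveys — so the hit table carries `total_reads × 0.6` rows while
RPKM is still normalized by the full library size. A configurable fraction
of emitted hits (default 5%) is planted below a retention threshold,
chosen uniformly among percent identity, query coverage, read length and —
for marker genes only — bitscore, because the bitscore floor applies only
to marker-gene alignments; planting a low bitscore on a non-marker hit
would not be filtered and would defeat filter-fidelity checks. Passing
hits are drawn strictly inside the retained region (coverage > 80.5,
identity ≥ the family threshold, bitscore ≥ 60), failing hits strictly
outside, so boundary behaviour is exercised only by dedicated fixtures.

**Reproducibility.** One `numpy` generator is derived per (table kind,
sample index) from the master seed via `SeedSequence([seed, stream,
sample])`, so adding samples or table kinds never perturbs previously
generated data, and identical configurations are bit-identical on rerun.

**What the generator does not emulate.** No read-level sequences or
sequencing errors (alignment is emulated at the hit-table level), no
chimeras, no compositional coupling between metagenome and
metatranscriptome beyond the shared abundances, no phylogenetic
autocorrelation of gene carriage, and no overdispersion beyond Poisson in
the taxon table. Tests passing on this generator therefore demonstrate
correctness of the estimators under their stated sampling models, not
robustness to real-data artefacts such as contamination or mapping bias.

## Functional profiling (`subshelf.profiling`)

Hit filtering applies, in order: read length ≥ 124 bp, query coverage
strictly > 80%, percent identity ≥ a per-family threshold (40% RHO; 60%
AtpA, AmoA, MmoA, CoxL, NxrA, NuoF, RbcL; 75% HbsT; 70% PsbA, YgfK, ARO,
IsoA; 80% PsaA; 50% otherwise), and bitscore ≥ 40 for single-copy marker
families. Coverage is strict-greater (the threshold is printed as ">80%"),
identity is greater-or-equal (bare percentages); both conventions are
documented here and configurable. One hit is retained per read — highest
bitscore, ties broken by lexicographic gene id — mirroring standard
DIAMOND top-hit practice; the choice matters only for reads with multiple
surviving alignments. The family threshold list is user-extensible because
curated databases differ in which subfamilies (e.g. [NiFe]-hydrogenase
groups) they retain.

RPKM is computed per gene as `(hits/length_kbp)/total_reads × 10⁶` and
summed within families. The single-copy-gene baseline is the arithmetic
mean of the 14 marker-family RPKMs; families with zero retained hits
contribute 0 rather than being dropped, which is conservative and keeps the
baseline comparable across samples. Copies per organism is family RPKM over
the baseline. Because the baseline is the marker mean, the mean marker
copies-per-organism is exactly 1 by construction; individual marker
families scatter around 1 with the binomial read-sampling error implied by
their expected hit counts (about 1–2% CV at 10⁵ reads). The cap-at-1 and
log₁₀(x+1) transforms are presentation-only and never feed back into
computation.

Metagenome and metatranscriptome hit tables take the same code path; only
the input differs.

## Genome-resolved quantification (`subshelf.genomes`)

TPM and CPM are the standard within-sample shares (each column sums to 10⁶
exactly). The Q2Q3 mean retains sorted positions `ceil(n/4) ≤ i <
floor(3n/4)` (0-based); for n ≤ 2 the slice is empty and the plain mean is
used, so a single value is returned unchanged. This convention — one of
several reasonable quartile rules — is fixed here and covered by tests
(values 1…8 → mean{3,4,5,6} = 4.5). Replicates are combined before
normalization: counts are summed, coverage vectors concatenated. The
RNA/DNA ratio uses the genome's summed TPM by default (`how="mean"` is
exposed); "expressed" means transcript count ≥ 1 unless overridden.

## CAZyme summaries (`subshelf.cazymes`)

Annotations are retained at e-value < 1e-15 and coverage > 0.35 (both
strict, matching the stringent convention for domain annotations).
Per-genome class counts tally distinct genes, so a multi-domain gene
contributes once per class it carries; CBM annotations are reported under
the display label CBD ("carbohydrate-binding domains"). "GH diversity" for
the top-genome ranking is the number of distinct GH families per genome —
the straightforward reading of family-level diversity — with ties broken
by genome id for determinism. All six classes (GH, GT, PL, CE, AA, CBM)
are computed; GH/GT/CBD are the default display set.

## Community ecology (`subshelf.ecology`)

All statistics are implemented from first principles on numpy; scipy
supplies only mid-rank and χ² primitives. scikit-bio and
scipy.cluster.hierarchy appear exclusively as independent oracles in the
test suite.

* **Rarefaction** draws without replacement (multivariate hypergeometric),
  default depth 15,400; shallower samples are dropped with a warning.
* **Chao1** uses the bias-corrected form `S + f₁(f₁−1)/(2(f₂+1))` by
  default; the classic `S + f₁²/(2f₂)` is exposed and falls back to the
  bias-corrected form at f₂ = 0.
* **UPGMA** merges the pair with the smallest average between-member
  dissimilarity, ties broken by smallest index pair. Node heights equal the
  merge dissimilarity and newick branch lengths are parent-minus-child
  height differences, making tip-to-root path lengths equal to the root
  height (ultrametric).
* **PERMANOVA** uses the sums-of-squared-dissimilarities pseudo-F with
  free permutation of sample labels (no strata). **IndVal** defaults to the
  group-equalized variant (specificity from group *means*), with the
  classic total-abundance weighting behind `group_equalized=False`; only
  singleton site-groups are scored (group combinations add nothing for
  two-group designs and are out of scope).
* **Permutation p-values** are `(b+1)/(n_perm+1)` for random permutations
  (seeded, reproducible) and the exact fraction of distinct relabelings —
  observed included — reaching the observed statistic when
  `n_permutations="exact"`. Statistic comparisons use a 1e-9 absolute
  tolerance so mathematically tied relabelings are not split by float
  noise; consequently a "perfectly separated" design yields the smallest
  p-value attainable given however many permutations reproduce the split.
* **Low-abundance filtering** for cross-study comparisons keeps taxa whose
  count strictly exceeds the threshold (default 4) in every sample; the
  strict inequality is deliberate and configurable.
* Grouping (e.g. basal layer vs mid-column, or cavity vs open ocean) is
  always a runtime input, never hard-coded.

Calibration, measured by the acceptance script at 999 permutations over
1000 exchangeable simulated tables: the expected rejection rate at
p < 0.05 is 49/1000 = 0.049, and both tests land within two standard
errors of it; a fourfold planted indicator at n = 6+6 is detected
(p < 0.05 and stat ≥ 0.5) in ≳99% of simulations.

## Biogeochemical budgets (`subshelf.biogeochem`)

Leucine incorporation converts to carbon production at 1.55 kg C per mol
leucine: 1 nmol Leu L⁻¹ d⁻¹ → 1.55 µg C L⁻¹ d⁻¹ → ×1000 (L→m³) → ÷12.011
(µg→µmol C) ≈ 129.0 µmol C m⁻³ d⁻¹. Rates are accepted per day or per hour
behind an explicit unit flag; nothing is guessed. The Arrhenius correction
`exp(−Ea/R·(1/T_to − 1/T_from))` (Ea = 72 kJ mol⁻¹ by default) is applied
to the leucine rate before carbon conversion; the order is commutative.

Turnover time divides standing biomass (cells mL⁻¹ × 10⁶ × cell carbon ×
10⁻⁹/12.011, in µmol C m⁻³) by production. The per-cell carbon content is
not printed alongside the bundled profile's turnover column; back-solving
that column gives 18–23 fg C cell⁻¹, so the default is a central 20 fg and
the CLI makes the parameter mandatory-explicit. Carbon demand is
production divided by growth efficiency (default 5%, typical of deep
oceanic waters), giving 6–12 µmol C m⁻³ d⁻¹ for the bundled profile's PHP
range of 0.3–0.6.

`scale_rate_by_concentration` is a deliberately minimal first-order helper
(`rate = ref_rate × conc/ref_conc`) for asking what rate a standing
substrate concentration could support relative to a reference measurement.
It is labelled as one plausible reading, not a validated kinetic model:
linear scaling of a published 62 nM d⁻¹ reference at 0.7 µM down to
0.44 µM gives ≈39 nM d⁻¹, and no attempt is made to reproduce estimates
built on unpublished assumptions.

## Problem sizes used in the bundled checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
1000-genome communities at 10⁵ reads for the recovery checks, 1000 random
tables for the normalization identities, 1000 simulated 10–20-taxon,
12-sample tables at 999 permutations for calibration, and ≤8-sample designs
for exact permutation enumeration. These sizes give sampling errors well
inside the asserted tolerances while keeping the full suite near ten
seconds of compute.

## Known limitations

* The hit-table emulation cannot surface alignment pathologies (paralog
  cross-mapping, database incompleteness); copies-per-organism accuracy on
  real data is bounded by the curation of the reference databases.
* The Q2Q3 and UPGMA tie conventions are fixed choices among equally
  defensible variants; results are insensitive for generic inputs but can
  differ on exactly tied data.
* PERMANOVA assumes exchangeability under the null; with strongly unequal
  group dispersions a significant result conflates location and dispersion
  (no PERMDISP is provided here).
* The budget helpers are deterministic arithmetic on measured means; they
  propagate no measurement uncertainty.
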