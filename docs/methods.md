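# Methods

## Scope

`ndj21` implements, end to end, the analysis used to find maternal genetic
risk factors for chromosome-21 nondisjunction from trisomic trio genotypes:
(1) a synthetic-cohort generator with known meiotic ground truth, (2) file
I/O and variant/sample quality control, (3) parent-of-origin and
MI/MII/mitotic stage inference, (4) the five association contrasts with
ancestry adjustment and multiple-testing support, and (5) a configurable
pipeline with machine-readable accounting. Genotype imputation, intensity-
based trisomic genotype calling, chromosomal-anomaly detection from LRR/BAF,
STR markers, X-chromosome analyses and the trisomic (chromosome-21) TDT are
out of scope; where the study design consumed their outputs (info scores,
call confidences) the package applies the corresponding quality filters to
values supplied in its inputs.

## Marker scoring and stage model

The child of a maternal trisomy-21 trio carries two maternal chromatids and
one paternal allele at every 21q marker. Scoring enumerates every
decomposition of the child's unordered allele triple into (maternal pair,
paternal allele) consistent with the parental genotypes. A marker is
*informative* when the mother is heterozygous and all consistent
decompositions agree on the pair's zygosity: reduced (R, two identical
maternal alleles) or not reduced (N). Decompositions that disagree leave the
marker *ambiguous*; a homozygous mother, missing data or no consistent
decomposition leave it *uninformative*. The same enumeration yields
parent-of-origin evidence: a marker supports maternal origin when the triple
is consistent with two maternal alleles plus one paternal but not with the
reverse. Origin is called by majority vote with a minimum evidence count
(default 3 markers) — the conventional reading of "unambiguous"
confirmation, since no explicit rule is standard.

Stage is decided by the informative zygosity nearest the centromere
(N → MI, R → MII), with three refinements:

* an all-R profile is classified **mitotic** and excluded; MII without any
  crossover is marker-indistinguishable from this class, so the simulator
  keeps the truth label MII while the inference deliberately classifies it
  mitotic (the equivalence is counted, not hidden);
* a single well-genotyped proximal R followed by a run of N's is accepted as
  MII regardless of the run-support setting, and flagged
  `single_marker_support`;
* `min_support` (default 1) controls how long a proximal run must be to
  decide the call; the default honours single-marker decisions because the
  markers are assumed well genotyped after QC.

Known failure modes on error-free data, both geometric and quantified by the
stage-recovery experiment: an MI trio whose first informative marker lies
distal to a crossover can read R at the pericentromere (≈0.5–1% at 200
markers/45 cM), and an MII trio whose only crossovers are very distal can
present all-R. Both rates fall with marker density, which the test suite
checks at 20/100/500 markers.

## Single-parent ratio classifier

With only the mother genotyped, a marker can never be resolved as
definitely-N: for a heterozygous mother, child dosages 1 and 2 always admit
both an R and an N decomposition, and only the extreme dosages 0 and 3 force
R. The "ratio of information" is therefore defined as

    ratio = (# markers whose every consistent decomposition is R)
            / (# partially informative markers)

over the `window_k` most centromere-proximal partially informative markers
(mother heterozygous, non-empty decomposition set). Error-free MI dyads
score ≈0; MII dyads score ≈ the paternal-allele match rate (≈0.4–0.5). The
MI/MII cutoff is trained exactly as in the study design: mask the father in
every staged complete trio, recompute the ratio, and grid-search midpoints
of the observed ratios for the cutoff maximising agreement with the
complete-trio calls (ties toward the smaller cutoff).

`window_k` defaults to 10. The window size is not fixed by the method's
description; the masking experiment — the design's own tuning instrument —
shows that a 20-marker partial-information window spans ~10 cM at the
default marker density, far enough from the centromere that MI trios with a
medial crossover acquire reduced-looking markers (training accuracy 0.94),
while a 10-marker window stays within ~2–3 cM and reaches 0.98. Father-only
families can have maternal origin confirmed (two maternal alleles
incompatible with the father) but not staged; their stage is undetermined,
and their fathers still serve as controls.

## Synthetic cohorts

The generator emulates the statistical structure the inference and the
association design assume; its defaults are the study conditions.

* **Population.** Balding–Nichols: ancestral frequencies Beta(1,1), per-deme
  frequencies Beta(p(1−F)/F, (1−p)(1−F)/F); default one deme, Fst 0.
  Genome-wide SNPs are independent (no LD), which suffices for PCA and
  regression calibration; block-correlated windows for Li–Ji checks are
  built directly in tests.
* **chr21 marker panel.** 200 q-arm markers on a 45 cM map by default. The
  map length is a configuration choice, not an estimate of the female 21q
  map. Marker frequencies are Beta(5,5) (heterozygosity ≈0.46), emulating
  panels selected for informativeness as used for stage phenotyping, unlike
  the genome-wide panel.
* **Meiosis.** Tetrad-level: two sister chromatids per homolog; crossover
  count Poisson with mean 2 × (arm length in Morgans) — the tetrad rate that
  makes the expected gamete map length equal the genetic map — positions
  uniform on the cM scale, each exchange between a uniformly chosen
  non-sister pair; no interference (Haldane). MI transmits one chromatid per
  homolog (whole-homolog model; premature sister separation is not
  modelled), MII both sisters of one homolog, mitotic one chromatid
  duplicated. Stage mix defaults to 0.75/0.23/0.02 (MI/MII/mitotic),
  matching the accepted ≥75%/≈25% split of maternal errors with a small
  post-zygotic remainder.
* **Ascertainment and risk loci.** Mothers are drawn by per-family
  rejection: a candidate mother is retained as a nondisjunction family with
  probability expit(baseline + Σ β·dosage), enriching risk alleles among
  mothers; fathers are drawn unconditionally, mirroring their role as
  population controls. With the default baseline logit of −3 (rare
  ascertainment) the mothers-vs-fathers logistic slope recovers β.
* **Observation model.** Each call is independently perturbed to a uniformly
  chosen different valid genotype with the error rate, then set missing with
  the missing rate; truth labels are untouched. Parent availability
  (complete / mother-only / father-only) defaults to 0.85/0.13/0.02,
  matching the dominance of mother-only among single-parent families.
* **Determinism.** One master seed; all streams derive from its
  `SeedSequence`. A fixed seed yields byte-identical cohort files.

What the simulator does **not** reproduce: linkage disequilibrium, realistic
allele-frequency spectra, genotyping-batch artifacts, maternal-age
structure, crossover interference and sex-specific maps. Passing tests
therefore demonstrate correctness of the algorithms under the stated model,
not robustness to every property of real array data.

## Quality control

Defaults follow the study thresholds: MAF ≥ 1% (computed on parents only for
chromosome 21, all genotyped samples elsewhere), exact Hardy–Weinberg test
p ≥ 1e-6 on parental genotypes, imputation info score ≥ 0.3 at the
imputation stage and ≥ 0.5 at the analysis stage (both retained as separate
thresholds), imputed calls below 90% confidence set missing *before* any
frequency is computed, and a 2% sample missing-call guideline surfaced as a
report. The HWE test is the standard conditional exact test, two-sided by
probability ordering (not mid-p), computed in log space and verified against
exact-rational enumeration for every table with ≤50 diploids. Mendelian
screening flags per-variant impossibilities and raises a chromosome-level
uniparental flag when a child shares no allele with one parent at ≥3 markers
and ≥1% of that chromosome's informative markers.

## Association

* **Contrasts.** all-mothers/MI/MII vs fathers, MI vs MII, plus a disomic
  TDT over complete trios (chromosome 21 is excluded from the TDT — the
  trisomic child genotype does not fit the disomic transmission count, and
  the trisomic TDT variant is out of scope). Trisomic genotypes never enter
  the logistic scans.
* **Model.** Per-variant additive logistic regression with intercept and
  three ancestry PCs, fit by batched Newton–Raphson (tolerance 1e-8 on the
  step, ≤50 iterations), complete-case per variant. Monomorphic variants are
  flagged and skipped; separation (|β|>15, non-finite SE or non-convergence)
  is flagged with no estimate — no Firth-type penalisation, as none is part
  of the design. Wald two-sided p-values for the SNP term. The implementation
  is cross-checked against statsmodels and against the closed-form
  contingency log-odds-ratio in the collapsible case.
* **PCA.** Patterson normalisation ((g−2p)/√(p(1−p)), missing mean-imputed),
  top three eigenvectors of the sample covariance, sign fixed by the
  largest-magnitude coordinate. SNP pre-selection: non-chr21 autosomes,
  missingness <5%, MAF >5%, configured exclusion regions removed (the four
  canonical high-LD regions must be pinned to a genome build by the user),
  then greedy LD pruning (window 50, step 5, r² ≤ 0.1 — conventional
  defaults, configurable).
* **TDT.** (b−c)²/(b+c) against χ²(1), counting B transmissions from
  heterozygous parents via hard calls (dosage-based counting; imputed
  dosages are not used). Families with Mendelian-impossible counts at a
  variant are skipped for that variant.
* **Inflation.** λ = median observed χ²(1) quantile / 0.4549.
* **Candidate loci.** Window = feature ± 60 kb; Meff from the Li & Ji
  eigenvalue rule on the absolute-value correlation matrix of control-group
  (fathers') genotypes in the window — controls avoid case-enrichment
  distortion; threshold 0.05/Meff per locus and analysis.
* **Top hits.** p < 1e-5 suggestive threshold; for each hit the minimum p
  within ±20 kb in every other analysis, NA when no variant is in range.
* **Negative control.** The identical logistic pipeline with sex as outcome
  on an unselected cohort, reporting λ and any genome-wide hits, to screen
  for male-vs-female artifacts inherent in using fathers as controls.

## Numerical and design choices

* Genotypes are int8 B-dosages (−1 missing); trisomic calls are B-dosages
  0–3, which encode the unordered allele triple losslessly.
* Distances are `position_bp − centromere_bp`, 1-based coordinates; all
  chr21 markers must be strictly distal to the centromere.
* The Li–Ji fractional part uses a 1e-9 guard so integer eigenvalues (exact
  duplicates) do not lose a full unit to floating-point floor.
* Grid cutoff ties resolve toward the smaller cutoff; degenerate single-
  value ratio distributions use that value as the only candidate.
* λ-based checks are sized so the median estimator (sd ≈ 1.4/√m on the λ
  scale) resolves the band being tested; the structure-adjustment experiment
  uses 30,000 SNPs for this reason.
* The pipeline manifest reconciles exactly: input families = MI + MII +
  mitotic excluded + undetermined + excluded for no genotyped parent;
  variant counts reconcile against the QC report per reason.

## Problem sizes

The bundled experiments use: 2,000 trios for stage recovery; 1,000 training
+ 500 held-out trios for the masking experiment; 500 vs 500 samples ×
10,000 SNPs (logistic) and 500 trios × 5,000 SNPs (TDT) for null
calibration; 100 replicates of 700 mothers vs 650 fathers for odds-ratio
recovery; 1,000 samples × 30,000 SNPs for structure adjustment; 950 samples
× 10,000 SNPs for the negative control; and a 700-family, 5,000-SNP demo
run for accounting. These sizes give each check the resolution it needs
while keeping a full run to a few minutes on one CPU.

## Known limitations

* Mother-only families cannot be screened for mitotic origin: the all-R
  signature maps to a high ratio and is called MII. Real designs confirm
  stage when the father is later genotyped.
* Paternal trisomies are not staged (the scoring is symmetric in principle
  but untested for that use).
* The uniparental-chromosome flag needs tens of markers per chromosome to
  have power; on very sparse panels it stays silent.
* With hard-call inputs only, info-score and confidence filters act on
  metadata supplied by upstream imputation rather than on values the package
  computes.
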