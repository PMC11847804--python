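# Methods

## Data model and ingestion

The package operates on the FAERS quarterly ASCII layout: six `$`-delimited
tables (DEMO, DRUG, REAC, OUTC, INDI, THER) with one header row and no
quoting, keyed by PRIMARYID (report version) and CASEID (case). Header names
are matched case-insensitively with era aliases (`age`/`age_cod`,
`gndr_cod`, `occp_cod`, `outc_cod`, …); columns absent from older eras parse
as missing, so schema drift changes missingness but never row counts. Files
are decoded as UTF-8 with a Latin-1 fallback. Lenient parsing (default)
skips and counts rows with the wrong delimiter count, since real quarters
contain stray rows; strict mode raises instead and is what the synthetic
fixtures use. Only the PRIMARYID-keyed layout (2012Q4 onward) is supported;
legacy ISR-keyed files are a documented limitation. THER is parsed but
unused downstream. Writing is the exact inverse: missing values serialize as
empty fields, and any field containing the delimiter or a newline is
rejected with the offending record named, making write-then-parse the
identity on valid bundles.

## Deduplication

Spontaneous-report cases appear in multiple versions. Per CASEID, the
report with the greatest FDA_DT is kept; ties are broken by the greatest
PRIMARYID, compared numerically when both values parse as integers and
lexicographically otherwise. Records with missing CASEID are retained as
singletons keyed by PRIMARYID. The operation is idempotent and reports its
removal count; every synthetic bundle checks that the post-dedup count
equals the generator's ground-truth report count.

## Cohorts

Pipeline order is fixed: deduplicate → drug/role match → age-stratum filter
→ join reactions, outcomes, indications and concomitants. Drug matching
normalizes names (uppercase, trim, collapse internal whitespace) and
compares both `drugname` and `prod_ai` against a synonym list under an
`exact` (default) or word-boundary `substring` policy, restricted to a role
set (default PS, primary suspect). Ages harmonize to years via YR ×1,
DEC ×10, MON ×1/12, WK ×7/365.25, DY ×1/365.25, HR ×1/8766 (Julian year);
a present value with a missing unit is taken as years; negative values and
unknown units are flagged invalid and excluded from age-defined strata,
with counts reported. Pediatric is the half-open interval [0, 18) years and
adult [18, ∞); reports with missing or invalid age belong to neither
stratum. Reaction joins collapse within-report duplicate PTs
(case-insensitively, after whitespace normalization), so the cohort's
`n_report_pt_pairs` is the sum over reports of distinct PT counts.
Concomitants are the drug rows of matched reports that are not themselves
(synonym AND role) matches.

Descriptive summaries use the cohort size as denominator for sex, age-band,
reporter, outcome and country percentages, and total concomitant mentions
(drug rows, not distinct reports) for concomitant percentages. Each report
contributes one outcome category by severity priority DE > LT > HO > DS >
OT, with CA and RI folded into OT; reports with no outcome row are counted
separately. Percentages round half-up to two decimals, the convention of
printed clinical tables. One published table in this literature prints
Death as 12.03% where its own counts give 59/474 = 12.45%; the package
always computes from counts.

## Disproportionality statistics

The counting unit is the (report, PT) pair, so the target-drug margin a+b
equals the cohort's pair total; report-level counting is available via
`counting="reports"`. For each PT with a ≥ 1, and each SOC after applying a
user-supplied PT→SOC mapping (MedDRA is licensed and never bundled;
unmapped PTs pool under a sentinel SOC and are reported):

* ROR = ad/bc with Wald 95% CI on the log scale. Zero cells make the
  statistic undefined rather than Haldane-corrected, because the a ≥ 3 gate
  makes such terms non-signals anyway.
* PRR = [a/(a+b)]/[c/(c+d)]; χ² = Σ(|O−E|−cc)²/E with expectations from the
  margins and cc = 0.5 (Yates) by default, 0 optionally.
* BCPNN: simplified point estimate IC = log2[aN/((a+b)(a+c))]; IC025 =
  E(IC) − 2√V(IC) using the Bate moment approximations with margin priors
  α₁ = β₁ = 1, α = β = 2, joint prior γ₁₁ = 1 and γ chosen so the prior IC
  expectation is zero at the observed margins. E(IC) converges to the
  simplified IC as N grows with cell fractions fixed (verified numerically
  at N = 10⁶). For a = 0 the point estimate is −∞ (flagged) while the
  moments remain finite.
* MGPS in relative-reporting-ratio form: EBGM = aN/((a+b)(a+c)) and
  EBGM05 = exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d)), a one-sided 90%
  lognormal bound. The full DuMouchel two-component gamma mixture is out of
  scope; the adopted form satisfies IC = log2(EBGM) identically, the
  pattern visible row-by-row in published tables of this kind, and obeys
  EBGM ≤ PRR ≤ ROR whenever ROR > 1.

A term is a signal when all four rules hold — ROR CI lower > 1; PRR ≥ 2 and
χ² ≥ 4; IC025 > 0; EBGM05 > 2 — and a ≥ 3. These thresholds are the
field-standard set and are exposed as configuration rather than hard-coded.
No multiple-testing adjustment gates signals; a Benjamini–Hochberg column
over the χ² p-values (statsmodels) is emitted for reference.

## Pediatric-vs-adult comparison

Per PT, the adult and pediatric cohorts' pair counts form a 2×2 table with
adults in the numerator: ROR = (a_adult/b_adult)/(a_child/b_child), so
ROR < 1 reads as relatively more reporting in children; a configuration
flag flips the orientation and every row carries an explicit direction
label. Significance uses the two-sided Fisher exact test, summing the
probabilities of all same-margin tables no more probable than the observed
one (relative tolerance 1 + 10⁻⁷, no mid-p), computed in log space via
`scipy.stats.hypergeom.logpmf`. The implementation agrees with
exact-rational enumeration to 10⁻¹² for all margins N ≤ 40 and with the
χ² approximation within 0.02 when all expected cells are ≥ 5. Directions:
child-dominant iff the ROR upper bound < 1 with p < α (default 0.05);
adult-dominant iff the lower bound > 1 with p < α; otherwise indeterminate.

## Synthetic data generator

The generator emulates the FAERS relational structure — duplicate CASEIDs
with perturbed FDA_DT, missing demographics, mixed age units, multiple drug
rows with role codes — with fully seeded, bit-reproducible output. Events
are independent Bernoulli draws per PT and report. For an injected PT with
background probability p and odds multiplier RR, exposed reports use
p′ = RR·p/(1−p+RR·p), making the true report-level odds ratio exactly RR —
the quantity ROR estimates. Reports drawing zero PTs are redrawn once, then
given a filler PT. This conditioning inflates marginal PT probabilities
(roughly symmetrically across arms), so expected case counts exceed the
naive n·p product; ground truth therefore records realized per-PT
exposed/unexposed counts, which a correct pipeline must match exactly.

Default conditions: 50% pediatric fraction; ages uniform within stratum
expressed through a YR/MON/WK/DY/DEC unit mix (sub-year units only for
children), floored at two decimals so unit round-trips never cross the
18-year boundary; 5% missing age; 10% duplicate case rate, half with older
FDA_DT and half same-date with a smaller PRIMARYID, exercising both dedup
tie-breaks; mean 3.6 concomitant mentions per report (the ratio observed in
real pediatric anesthetic cohorts, ≈1,714 mentions per 474 reports); an
anesthesia-flavoured 25-PT vocabulary with background probabilities 0.004 -
0.03. What the generator does not emulate: drug co-prescription
correlations, temporal reporting trends, event-event dependence, and
real-world name misspellings — so passing recovery tests demonstrates
correctness of the pipeline arithmetic and gating, not robustness to every
real-data pathology.

## Validation study sizes

Chosen as the package's own benchmark conditions:

* Flagging run: 200,000 reports, target-drug probability 0.02, three PTs
  injected at odds ratio 10 with p = 0.01 among 50 null PTs — all three
  must be flagged by all four rules, with at most 3 nulls flagged.
* Estimator consistency: 100 seeds at odds ratio 5, 20,000 reports each —
  the median estimated ROR must fall in [4.0, 6.0] and the 95% CI cover the
  truth in 93–97% of seeds (Monte Carlo SE ≈ 2.2% at 100 seeds).
* Comparison calibration: 200 seeded replicates of a symmetric null at
  2,000 reports — significance in at most 10%; a child-only odds ratio of 8
  must always be detected child-dominant.

## Numerical choices and edge cases

χ² uses max(|O−E|−cc, 0) per cell; empty tables are rejected at
construction; an all-zero Fisher table returns p = 1 by convention; empty
cohorts propagate as empty result frames with warnings rather than errors;
presentation CSVs round to 2 decimals while `*_full.csv` retains full
precision; all iteration orders are deterministic so repeated runs are
byte-identical.

## Known limitations

No legacy (pre-2012Q4) FAERS layouts; no MedDRA hierarchy beyond the
user-supplied PT→SOC mapping; no dose analysis (dose fields are mostly
missing in practice); no stratified or covariate-adjusted MGPS; no
country-name harmonization; duplicate detection is exactly the CASEID rule,
not probabilistic record linkage.
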