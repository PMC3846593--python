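# Methods

## Study design being modelled

The pipeline targets a pooled two-group label-free proteomics design:
semen specimens are screened (semen parameters, Endtz leukocyte test,
seminal ROS chemiluminescence), specimens with Endtz counts above
1×10⁶ WBC/mL are excluded as likely infected, and the remainder are
pooled into ROS− (< 20 RLU/sec/10⁶ sperm) and ROS+ (≥ 20) groups. Each
pool is measured once by LC-MS/MS, searched with two engines, and
proteins are compared between pools by normalized spectral counts.
Because each pool is a single pooled sample there are no replicates and
no p-values at the protein level; the 2-fold rule stands in for a
significance test.

Boundary conventions are taken literally from the strict inequalities
that define the groups: a sample at exactly the ROS threshold is ROS+
(only "< threshold" is ROS−), and a sample at exactly the Endtz limit is
included (only "> limit" is excluded). Percentiles use linear
interpolation between closest ranks; missing numeric fields are rejected
at load rather than imputed, except the antioxidant-capacity and
DNA-fragmentation fields, which are optional because they are measured
for patients only.

## Identification and tallying

The entry point is per-engine PSM tables (TSV), not raw spectra: raw
data for this design are typically unavailable, and the consensus and
quantification logic starts from identifications. A protein is accepted
only if both engines identify it (set intersection), assessed per
protein across pools. Spectral counts are tallied per engine and
combined per (protein, pool) by the per-engine **maximum** by default:
identification is validated by both engines, but summing would count the
same spectrum twice wherever both engines matched it. The combination is
configurable (`a`, `b`, `max`, `sum`) because which engine's counts feed
quantification is a free choice in this design.

Peptides shared between proteins are credited to every matching protein
(no razor/parsimony logic); with shared peptides this inflates both
proteins' counts, which users should keep in mind for homologous
families such as the semenogelins. Sequence coverage is the residue
union of the PSM start/end intervals (1-based, closed); PSMs without
positions contribute to counts but not coverage, which is then a lower
bound.

## Quantification

NSAF per pool: nsc_i = (sc_i/L_i)/Σ_j(sc_j/L_j). The normalization
wording "total spectral counts and the number of amino acids" also
admits sc/(L × total); both are implemented (`--norm
nsaf|sc_per_len_total`) with NSAF the default as the standard
operationalization. The ratio is oriented ROS+/ROS−. No pseudocount is
added by default — zero counts route to the unique-to-one-pool
categories instead of producing infinite ratios; `--pseudocount` offers
shrinkage for users who prefer finite ratios everywhere. The fold
threshold applies to the ratio (≥ 2 or ≤ 0.5, i.e. |log2| ≥ 1) and log2
values print to 3 decimals.

A known tension in this calling scheme: with a strict 2-fold rule,
ratios such as 1.338 or 0.753 are "unchanged" even when a narrative
might describe them as up- or down-regulated. The strict rule is
implemented; the table output reports the ratio so readers can apply
their own threshold.

## GO summaries and enrichment

Annotations come from a packaged static gene→GO-slim TSV (curated by the
package authors from public generic GO-slim resources) rather than live
web queries, for reproducibility. Set summaries count genes per term
within each aspect, with an explicit `unannotated` bin; the three
protein sets (ROS−-unique, ROS+-unique, common) must be disjoint.
Enrichment is the right-tailed Fisher exact test: p = P[X ≥ overlap]
for X hypergeometric(background, |set|, |dataset|), with ratio =
overlap/|set|. The background universe defaults to the genes of the
annotation map and is overridable; reported p-values therefore depend on
that choice and are not comparable across backgrounds.
Benjamini–Hochberg q-values are reported alongside raw p-values.

## Synthetic-data generator

The generator emulates the pooled design so every stage can be tested
against known truth. Its components and defaults:

* **Proteome** — random sequences over the 20 amino acids, lengths
  uniform on 100–400 residues (typical of secreted seminal proteins up
  to mid-size glycoproteins), 100 proteins by default.
* **Digestion** — in-silico trypsin: cleave after K or R unless followed
  by P; fragments shorter than 6 residues are kept for positional
  bookkeeping but excluded from the detectable set (short tryptic
  peptides are rarely identified); missed cleavages configurable (0 by
  default).
* **Counts** — per (protein, pool) spectral counts are Poisson with
  mean depth × a_i L_i / Σ_j a_j L_j, where a is relative abundance:
  the expectation is proportional to abundance × length, which is
  exactly the premise under which NSAF is the matched, unbiased
  estimator. The length exponent is configurable to probe model
  misspecification. Default depth is 5×10⁴ spectra per pool, which
  keeps expected per-protein counts comfortably above 20 under the
  default effect grid.
* **Effects** — true fold changes sit on a {±1, ±2} log2 grid and are
  assigned in a *compositionally balanced* design: each protein raised
  2^m-fold is offset by 2^m proteins lowered 2^m-fold, so total
  abundance mass is conserved and the relative-abundance ratio of an
  unchanged protein is exactly 1. Without this balance, closed
  normalization shifts every apparent ratio by the net mass change and
  "unchanged" loses meaning. Defaults: 8% of proteins up 2-fold (each
  offset by two down 2-fold), 4% up 4-fold (each offset by four down
  4-fold). Base abundances are equal by default (`abundance_sigma = 0`);
  a log-normal spread is available, at the cost of small compositional
  offsets in the realized truth. Ground truth is always recorded as the
  realized per-pool relative abundances and their log2 ratios, so truth
  and estimand live in the same (compositional) space for any setting.
* **Uniques** — 3% of proteins are present only in the ROS− pool and 3%
  only in the ROS+ pool (mirroring the handful of pool-unique proteins
  seen in small seminal-plasma panels); unique proteins carry no fold
  change.
* **Engines** — each spectrum is observed by engine A with probability
  0.95 and engine B with 0.90, independently: two good but imperfect
  engines with realistic overlap. Engine scores are uninformative
  positive numbers and are not used by any default filter.
* **Cohort** — sample metadata with log-normal ROS (donor median ≈ 4,
  patient median ≈ 100 RLU/sec/10⁶ sperm, long right tails), Endtz-
  positive specimens injected among patients at rate 0.075, and semen
  parameters drawn near the reported donor/patient envelopes. 20 donors
  and 32 patients by default.

Everything is driven by one `numpy` Generator seeded from the config, so
identical configs produce byte-identical output files.

**What the generator does not emulate:** peptide detectability and
ionization efficiency differences, retention-time structure, dynamic
range compression, shared/homologous peptides, protein inference
ambiguity, or any spectrum-level noise beyond Poisson counting and
engine dropout. Passing the recovery tests therefore demonstrates that
the pipeline's arithmetic and calling logic are correct under the
spectral-counting model's own assumptions — not that NSAF ratios from
one pooled run are unbiased on real instruments.

## Test and validation sizes

The parameter-recovery check runs 50 seeded replicates of the default
100-protein experiment at depth 5×10⁴ per pool with perfect engine
detection, verifying that expected per-protein counts stay ≥ 20, that
the sign of the estimated log2 matches truth for at least 95% of
proteins with true |log2| ≥ 1, that the median absolute log2 error is
≤ 0.3, and that pool-unique memberships are recovered exactly. The
Fisher implementation is checked against a brute-force hypergeometric
tail enumeration for every parameter combination with background ≤ 30
(tolerance 1e-10), and coverage against a boolean-mask oracle on 1000
random interval sets. These sizes were chosen to make the checks sharp
while keeping the suite quick to run.

## Reference fixtures

The packaged evidence fixture stores per-pool distinct-peptide counts,
coverage and engine scores for the 14 reference proteins; raw spectral
counts were never published, so peptide counts serve as count proxies.
Presence/absence — and hence the unique/common set structure — is exact
under the proxy; numeric ratios computed from it are illustrative only,
which is why the published NSC ratios and log2 values are stored
verbatim in a second fixture rather than recomputed. Protein lengths for
the fixture are estimated from printed molecular weights at 110
Da/residue. The printed tables disagree on two accessions (clusterin,
semenogelin I isoform); each fixture keeps its source values verbatim
and gene symbols reconcile them.

## Known limitations

* Single pooled sample per group: no variance model, no protein-level
  inference; the 2-fold rule is a heuristic, not a test.
* Peptide-count proxies in the reference fixture make fixture-derived
  ratios non-comparable to the published ones.
* No parsimony for shared peptides; counts of homologous proteins can
  be inflated.
* Enrichment p-values depend on the background-universe choice, which
  is user-supplied.
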