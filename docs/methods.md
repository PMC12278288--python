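# Methods

## Pipeline model and assumptions

The pipeline treats a countries × indicators table as three independent
"views" (themes) of a latent per-country risk level.  Its stages and the
assumptions behind them:

1. **Completeness screening.**  Countries with any missing indicator are
   removed, never imputed.  Indicators come from heterogeneous national
   statistics; imputation would inject artefactual covariance into the
   distance structure k-means clusters on.  Screening is idempotent and
   reports every dropped country with its missing columns.

2. **Standardization (per variable, post-screening).**  Two modes:
   `center` (subtract the column mean) and `zscore` (additionally divide
   by the sample SD, denominator n−1).  **Default: `zscore`.**  The
   indicator scales differ by three orders of magnitude (all-cause DALY
   rates ~10⁴ vs egg protein ~10⁰ g/day); on merely centered data the
   Euclidean objective is dominated by the large-scale columns and the
   "multivariate" clustering degenerates to clustering on one or two
   variables.  `center` is retained for literal replication of analyses
   that describe scaling as mean subtraction only; both are exposed in
   the config and the chosen mode is recorded in the run manifest.
   Zero-variance columns under `zscore` become all zeros with a logged
   warning (a constant carries no clustering information either way).

3. **k-means (in-repo).**  Lloyd's algorithm with k-means++ seeding,
   best-of-`restarts` by final WSS.  Defaults: 50 restarts, iteration cap
   300, convergence = exact assignment stability.  Restart *r* uses an
   independent generator seeded `seed + r`, making the whole fit
   reproducible and the restart set embarrassingly parallel in
   principle.  An emptied cluster is reseeded with the point farthest
   from its assigned center.  Correctness anchors: WSS is monotone
   within a restart; on all tiny instances (n ≤ 8, k ≤ 3) best-of-50
   restarts attains the exhaustive-partition minimum; on larger fixed
   inputs the WSS matches scikit-learn's best-of-restarts within 1e-6
   relative (scikit-learn is used only as a test oracle).

4. **Cluster-count selection.**  The elbow scan records W(k) for k in a
   configured range (default 1..6).  The automated elbow is the interior
   k maximizing the second forward difference of **log** W(k).  The raw
   second difference systematically picks the first merge of
   well-separated groups (for three near-collinear, equally spaced
   group centers it scores k=2 about twice as high as k=3); on the log
   scale the criterion asks where the *relative* reduction collapses,
   which recovers the planted tier count reliably.  A range with no
   interior point returns k_min with a warning.  Silhouette coefficients
   (standard (b−a)/max(a,b), Euclidean, singletons scored 0) are
   computed for validation and recorded; the pipeline honors the
   configured k (default 3) and records the curve rather than silently
   overriding it.

5. **Risk-ordering.**  Raw k-means labels are arbitrary.  Each cluster
   gets a severity score: the mean over its countries of the
   direction-aligned z-scored theme variables, where each variable
   carries a severity direction (+1: higher is worse, e.g. anemia
   prevalence; −1: higher is better, e.g. life expectancy).  Labels are
   reassigned 1..k in increasing severity, so label k is the worst-risk
   cluster; ties break by cluster size (larger → lower label), then
   original index.  For the default indicator set the affluence-associated
   burden variables (alcohol- and BMI-related death shares, neoplasm
   incidence) carry −1, matching their observed profile across published
   cluster means.

6. **Multiview matching and late integration.**  Cross-theme concordance
   is measured on membership sets with the Jaccard coefficient
   |A∩B|/|A∪B| (undefined — an error — for two empty sets).  The
   high-risk match maximizes the sum of the three pairwise Jaccards over
   all k³ label triples (exact, 27 candidates at k=3); whether the
   winner coincides with the worst-risk triple (k,k,k) is logged.  Late
   integration always decomposes the *worst-risk* clusters — the
   scientific target is the highest-risk countries — while the max-sum
   triple is reported as a concordance diagnostic; on symmetric
   synthetic tiers the diagonal triples score near-identically, so the
   max-sum winner is an arbitrary tier and would be the wrong
   integration target.  The Venn partition comprises the 7 exclusive
   regions; percentages are region size / union size × 100.  Reported
   Jaccards and percentages round half-up (2 dp / 1 dp) to match
   conventional table formatting; full precision is kept internally.

7. **Contribution statistics.**  Per variable, on screened
   *unstandardized* values against its own theme's risk-ordered labels:

   * **Shapiro–Wilk** (delegated to scipy) flags normality at p ≥ 0.05.
     The flag is reported rather than used to switch methods silently:
     both the rank-based and the robust statistic are always computed.
   * **Kruskal–Wallis H** (in-repo): mid-ranks for ties,
     H = [12/(N(N+1))] Σ nᵢ(R̄ᵢ−(N+1)/2)², divided by the tie correction
     1 − Σ(t³−t)/(N³−N); p from χ²(k−1).  All-identical values give
     H=0, p=1 by convention.  H is invariant under strictly monotone
     transformations.
   * **Robust R²** (in-repo MM estimator): the one-way cluster-means
     model is fit by an S-estimate — bisquare M-scale with tuning
     c₀ = 1.5476 (50% breakdown), initialized at group medians and
     refined by IRLS — followed by an M-step at the fixed S-scale with
     c₁ = 4.6851 (95% Gaussian efficiency).  The reported statistic is
     the weighted robust R² = 1 − Σwᵢrᵢ² / Σwᵢ(yᵢ−ŷ_w0)², with wᵢ the
     final IRLS weights and ŷ_w0 the w-weighted grand mean, clipped to
     [0,1].  Several robust-R² definitions exist; this one is adopted
     because it reduces to the classical one-way R² when no observation
     is downweighted, which is tested (agreement within 0.05 on clean
     Gaussian one-way data) along with stability (< 0.1 movement under
     5% gross contamination, where OLS R² collapses).
   * One-way *variable-on-cluster* regression is the only orientation
     that yields a per-variable explained variance, and is what is
     implemented.
   * No multiple-testing correction by default; a Benjamini–Hochberg
     adjusted-p column is optional (`bh=True` / `--bh`).

## Synthetic data generator

The generator emulates exactly the structure the pipeline assumes — and
deliberately nothing more.  Each country draws a uniform latent
reference tier in 1..n_tiers (default 3; tier n_tiers = worst).  The
first theme realizes the reference tier; each other theme keeps it with
probability 1−`discordance` and otherwise resamples uniformly from the
remaining tiers, so `discordance` is exactly the per-country flip
probability and the planted worst-tier Jaccard between themes shrinks
predictably as it grows.  Each variable draws, once per dataset, a base
mean from [10, 70], a within-tier SD from [1, 8] (module constants on
the scale of protein-like indicators), and a random severity direction;
tier t's mean sits at `direction · (t − (T+1)/2) · tier_separation · SD`
from the base, with i.i.d. Gaussian noise.  Cells are masked
independently at `missing_rate`.  One seed sequence per dataset is split
into independent substreams (tiers, means, noise, masking), so toggling
masking never perturbs the planted tiers.  Defaults mirror the reference
analysis's shape: themes (NAD,14), (HAD,8), (HALE,3), three tiers.

What it does **not** model: between-indicator covariance within a tier,
skewed or heavy-tailed indicator distributions, country-size weighting,
or temporal structure.  Passing recovery tests on this generator
demonstrates the pipeline's correctness under its own assumptions — not
that real country data satisfies those assumptions.

## Reference membership lists

The packaged fixture transcribes a published per-theme three-cluster
assignment of 168 countries (cluster sizes NAD 61/42/65, HAD 45/69/54,
HALE 27/88/53), validated on load by size checksums and the
shared-universe invariant.  Country names are stored in canonical
display form (straight apostrophes, no leading article); the
canonicalizer folds case and diacritics and applies a fixed alias table,
and is idempotent.  One documented discrepancy: the lists imply a
HAD&HALE-only Venn region of 4 countries (Gabon, Kiribati, Myanmar,
Papua New Guinea), while the source's prose names 5 there (adding Laos)
— but the same lists place Laos in all three worst clusters, i.e. in the
triple intersection, and the prose's region counts would sum past its
own printed union size.  The lists are authoritative here; the
HAD&HALE-only count is therefore not among the replay checks.  The
source also announces one fewer indicator than its variable lists
enumerate (14+8+3 = 25); the enumerated lists are used.

## Problem sizes and numerical choices

* Recovery tests use n = 200 countries, separation 6, discordance 0.1,
  20 seeds — large enough that ARI ≥ 0.95 and elbow-k = 3 are stable
  properties, small enough to run in seconds.
* Exhaustive oracles: k-means vs full-partition enumeration at n ≤ 8,
  k ≤ 3 (200 instances); Venn regions vs per-country classification
  (500 random triples); Kruskal–Wallis vs full permutation enumeration
  at total n ≤ 7.  For the last, the exact permutation distribution is
  discrete with large atoms, so the continuous χ² p is compared to the
  exact **mid-p** (half-weight on the observed atom) within 0.15, the
  scale of the χ² approximation error at such sizes.
* Kruskal–Wallis calibration: type-I error at nominal 0.05 over 2000
  null replicates (3 groups × 30) within 3 binomial SDs.
* WSS consistency tolerance 1e-9 relative; assignment ties (equidistant
  centers) resolve to the lowest center index; best-of-restarts ties
  keep the earliest restart.
* The M-scale fixed point and IRLS iterate to relative tolerance 1e-9
  with generous iteration caps; a group whose observations are all
  fully downweighted keeps its previous estimate rather than dividing
  by zero.

## Known limitations

* Exact replication of published memberships from raw indicator data is
  out of reach in principle: initializer, restart count, and seed of the
  original analysis are unknown, and the raw table is not packaged.  All
  set-arithmetic results are instead recomputed exactly from the
  published membership lists.
* The elbow criterion, like all of them, is a heuristic; it is recorded
  alongside silhouettes rather than trusted blindly, and the pipeline
  honors the configured k.
* The robust R² definition is one of several in use; values are
  comparable within this pipeline, not across robust-R² conventions.
* Silhouette computation is O(n²) memory in the distance matrix — fine
  for country-scale n, not for n ≫ 10⁴.
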