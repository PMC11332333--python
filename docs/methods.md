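# Methods

## The analysis

`phyloprof` implements marker-anchored phylogenetic profiling for bacterial
genomes. The marker is a structured non-coding RNA — the motivating case is
the OLE ("ornate, large, extremophilic") RNA of Bacillota — detected by a
covariance-model homology search across a large set of genome assemblies.
Genomes are sorted into a marker-positive cohort (carrying a full-length
copy of the marker gene) and a marker-negative cohort (carrying none), and
every protein family is scored for how strongly its presence/absence
pattern tracks the marker. Families enriched in the positive cohort are
candidate functional partners of the RNA; families depleted there are
candidate functional replacements.

The pipeline runs in six stages:

1. **RNA hit triage.** Covariance-model hits are classified from
   (bit score, truncation flag) alone:

   | category     | condition                                            |
   |--------------|------------------------------------------------------|
   | full_length  | nontruncated, bits ≥ 390.0                            |
   | variant1     | nontruncated, 310.0 ≤ bits < 390.0                    |
   | variant2     | nontruncated, 235.0 ≤ bits < 310.0, **or** truncated, bits ≥ 235.0 |
   | unclassified | everything else                                      |

   Lower bounds are inclusive, upper bounds exclusive. The defaults (390 /
   310 / 235 bits) were read off the bit-score histogram of the original
   search and are exposed as `ClassificationThresholds`; the
   `score_histogram` helper supports choosing different cutoffs for a
   different marker. One deliberate and perhaps surprising consequence of
   the truncation rule: a truncated hit is variant2 *no matter how high it
   scores*, because a clipped alignment cannot attest a full-length gene.

2. **Per-assembly status.** An assembly's status is the category of its
   best classified hit (highest bit score; exact ties broken by category
   precedence full_length > variant1 > variant2, then by target sequence
   id). The multi-hit resolution rule is this package's own choice — the
   classification rules themselves are stated per hit — and is
   deterministic and order-independent by construction. Unclassified hits
   count as no evidence and never exclude an assembly.

3. **Cohorts.** Marker hits outside the allowed phylum (default
   `Bacillota`) are excluded as likely assembly/taxonomy artifacts
   (`outside_taxon`). Variant carriers are excluded from both cohorts
   (`variant_carrier`): they carry *some* marker, so they are evidence for
   neither presence nor absence of the full-length form. The species tree
   is pruned to the smallest clade (MRCA subtree) containing all
   marker-positive assemblies; the analysis universe is the in-phylum tip
   set of that clade, so the negative cohort is "assemblies inside the
   marker's phylogenetic span that lack it" rather than all of bacteria.
   In-phylum variant carriers outside the clade are recorded as
   `not_in_universe`. `universe_mode="whole_phylum"` instead takes every
   in-phylum assembly; both denominators are defensible and the choice is
   explicit in the config and the manifest.

4. **Protein families.** Three constructions, all yielding sets of
   (assembly, protein) members:
   * *reference-query hits*: one family per query protein, members are all
     subjects with e-value ≤ 1 × 10⁻¹⁰ (inclusive, matching the search
     tool's own ≤ filter; the cutoff empirically separates likely homologs);
     overlapping families from different queries are **not** merged,
     because merging would change the family count and the scatter plot's
     point set;
   * *cluster map*: one family per cluster representative, clusters with
     fewer than 5 proteins discarded;
   * *profile-HMM hits*: members with full-sequence bit score ≥ a
     per-model floor. The floors are judgment calls made by inspecting
     bit-score histograms and gene context; the package deliberately does
     not automate that judgment and instead requires explicit per-model
     values (`FamilyBuildParams.hmm_bit_min`).

   Presence is defined as ≥ 1 member; the same member sets drive paralog
   counting (`count_paralogs`), so presence and copy-number analyses share
   one source of truth.

5. **Statistics.** For each family, the 2×2 table of marker status ×
   family presence over the two cohorts gives cohort presence fractions
   f_pos = n₁₁/(n₁₁+n₁₀), f_neg = n₀₁/(n₀₁+n₀₀) and the mutual
   information in bits

       I(X;Y) = Σ_{x,y∈{0,1}} p_xy · log₂( p_xy / (p_x · p_y) ),

   evaluated as the expanded four-term sum with marginals from the cell
   sums. Two zero-handling conventions:
   * `discard` (default): the statistic is *undefined* whenever any
     logarithm operand is zero or undefined, i.e. any empty cell. This is
     the historically faithful rule, but note it silences exactly the
     perfect-association tables (n₀₁ = n₁₀ = 0), the strongest signals.
   * `limit`: the standard 0·log 0 = 0 convention; perfect association
     scores min(H(X), H(Y)) bits, degenerate marginals give 0.

   Undefined-MI families are retained and flagged (`NA` in the report),
   ranked after all defined ones, never dropped — so the fraction scatter
   stays complete. Ranking is by MI descending, ties by |f_pos − f_neg|
   descending, then family id.

6. **Report.** A ranked TSV (one row per family: fractions, table cells,
   MI, direction, rank), the cohort lists with per-assembly exclusion
   reasons, the presence matrix, and a manifest with input digests and
   stage counts. Floats are printed with 6 significant digits; full
   precision is kept internally. Reruns are byte-identical.

## The synthetic generator

`phyloprof.simulate` generates the structures the analysis assumes, so the
whole pipeline is testable without any genome download:

* a random bifurcating tree over the cohort assemblies, with
  marker-positive tips grouped into at most `n_clades` monophyletic clades
  (default 3), emulating a marker concentrated in distinct clades of one
  phylum; branch lengths are exponential with mean 0.1
  substitutions/site — arbitrary but in a realistic range;
* per-assembly marker statuses, plus 2 decoy out-of-phylum carriers and 2
  variant carriers by default so every exclusion path is always exercised;
* families whose presence is an independent Bernoulli draw per assembly
  with cohort-conditional probability (null families use 0.5/0.5), and
  per-assembly member counts of 1 + Poisson(paralog_mean) when present, so
  presence always implies count ≥ 1;
* mock search-output files in the real tools' formats. Emitted bit scores
  are drawn inside the correct category band for each status (truncated or
  low-scoring for variant2 carriers, ≥ 390 for full-length), family
  members get e-values ≤ 1 × 10⁻¹⁰ and deliberate decoy hits get larger
  ones, so parsing + classification + filtering must all be correct for
  the pipeline to reproduce the recorded truth exactly.

The ground truth (`SimTruth`) — including the expected analysis universe —
is derived inside the simulator with plain set logic and a brute-force
root-to-tip path-intersection MRCA, independent of the dendropy-based
route the pipeline uses, so end-to-end identity tests compare two
genuinely different implementations.

What the generator does *not* emulate: phylogenetic autocorrelation of
family presence (draws are independent given the cohort, whereas real
gene content is correlated along the tree), horizontal transfer, genome
incompleteness, and actual sequences. Passing tests therefore demonstrate
the correctness of the bookkeeping and the statistics on the assumed
generative model, not robustness to real-data artifacts such as
tree-induced pseudo-replication — the same caveat applies to naive
phylogenetic profiling generally.

## Numerical and design choices

* All cutoff comparisons are inclusive on the side the tools themselves
  use (≥ for bit scores, ≤ for e-values).
* MI is computed in log base 2, fixed; `limit` mode clips the ≤ 1 ulp
  negative residue that floating point leaves on exactly independent
  tables to 0.
* Coordinates stay 1-based inclusive as emitted by the search tools; no
  conversions at parse time.
* Every ordering that reaches an output file is explicitly sorted;
  tie-breaks are lexicographic; reruns are byte-identical.
* A single integer seed drives each simulation through per-stage child
  generators (`default_rng([seed, stage])`); no global RNG state.
* Degenerate inputs fail loudly: empty cohort sides, statuses outside the
  universe, duplicate tree tips, members under two cluster
  representatives, missing taxonomy rows and missing per-model HMM floors
  are all errors, not warnings.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
cohorts of 300+300 assemblies with 206 families for signal-recovery
checks, 20 independent seeds of a 16-assembly cohort for end-to-end
fixture identity, 1,000 random contingency tables for the MI oracle
cross-check, and 500 random topologies (≤ 12 tips) for MRCA pruning
against the brute-force oracle. These sizes give stable statistical
behaviour while keeping a full run in seconds. Full-scale replication on
~17,000 genomes (GTDB R08-RS214 plus a published covariance model) uses
the same code paths via the file-based CLI but requires those external
inputs; the headline counts from that dataset are not reproducible from
synthetic data and are not claimed by the tests.

## Known limitations

* MI ranks carry no significance calibration (no p-values or
  multiple-testing control); ranking is descriptive, as in the original
  analysis design.
* Profiling is not phylogenetically corrected: clade-correlated gene
  content inflates apparent association. The tree is used only to bound
  the universe.
* The discard-mode MI is reported faithfully but is a poor ranking
  statistic when perfect associations exist; use `limit` mode for
  discovery and `discard` only for fidelity to the original rule.
* The cluster-map route applies the size-5 floor to protein counts before
  assembly resolution; unresolvable members can shrink a family below the
  floor after the fact.
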