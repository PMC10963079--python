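# Methods

## Network model

Nodes are binary diseases identified by phecodes.  Two edge-generating
mechanisms are modelled:

* **Direct (shared-SNP) edges.**  For each disease, the significant SNP set
  is the variants with association p < 5×10⁻⁸ (strict inequality; boundary
  ties are excluded) and minor allele frequency min(eaf, 1−eaf) > 0.05.  The
  MAF rule is evaluated per disease table, so a shared edge requires the
  variant to pass in *both* diseases.  E contains every unordered disease
  pair with a non-empty intersection of significant SNP sets; the edge
  stores the full sorted intersection.
* **Indirect (endophenotype) edges.**  The genetic correlation of every
  disease×biomarker pair is estimated (below); pairs where either phenotype
  is not confidently heritable are discarded before multiple-testing
  correction; one Benjamini–Hochberg procedure at FDR 0.05 then runs jointly
  across all surviving pairs.  The resulting binary association matrix R̂
  induces, for each biomarker, a clique on its associated diseases.  Because
  R̂ is binary, the sign of the underlying correlations cannot influence the
  rule; signed r_g values are preserved in the reports only.

The merged graph Ẽ = E ∪ E⁺ is undirected and unweighted.  Edges are
classified direct / indirect / both; the identities |Ẽ| = |E| + |E⁺ \ E| and
"classes partition Ẽ" are asserted on every merge.  Isolated nodes stay in
the graph so that connected-node counts are meaningful.

## Heritability and genetic correlation

For variant j with LD score l_j, sample size N and panel size M, the model
moments are E[z²_j] = N·h²·l_j/M + 1 and, for a pair of phenotypes,
E[z₁ⱼz₂ⱼ] = √(N₁N₂)·ρ_g·l_j/M + c with ρ_g = r_g√(h²₁h²₂); the free
intercepts absorb confounding and sample overlap.  Estimation:

1. **Two-step weights.**  A unit-weight pass gives fitted means f_j.  The
   second pass uses w_j = 1/(2·ṽ²_j) for z² regressions and
   w_j = 1/(ṽ₁ⱼṽ₂ⱼ + c̃²_j) for the product regression, where
   ṽ = max(|f|, 1) and c̃² = max(f², 1).  The floors keep weights bounded
   when a fitted mean dips below 1, and they make the product regression of
   a table with itself coincide *exactly* with its h² regression — hence
   r_g(t, t) = 1 identically, a useful self-consistency invariant.
2. **Block jackknife.**  Variants (in genome order after harmonization) are
   split into 200 contiguous blocks (configurable; reduced automatically if
   fewer variants than blocks).  Each delete-one replicate re-fits all
   regressions from cached block sums with the full-sample weights held
   fixed; the r_g SE jackknifes the complete ratio ρ̂_g/√(ĥ²₁ĥ²₂), so
   denominator noise is propagated.
3. **Reference distribution.**  p-values refer r̂_g/SE to a Student-t with
   n_blocks−1 degrees of freedom.  A normal reference is measurably
   anti-conservative exactly where it matters — BH rejections among nulls
   are driven by the far tail — while the t reference matches the excess
   kurtosis the jackknife induces.
4. **Heritability filter.**  A pair enters FDR only if both ĥ² > 0 and both
   jackknife z-scores ĥ²/SE ≥ 4 (configurable).  Binary-trait h² is
   reported on the observed scale only; the edge rule needs significance,
   not scale, so liability conversion is out of scope.  r̂_g outside [−1, 1]
   from sampling noise is kept raw internally and clipped to ±1.25 in
   output files.

Known behavior: in marginally heritable regimes (h² z-score near the filter
threshold) the jackknifed ratio test is conservative, because denominator
noise inflates the SE; its size is accurate in the confidently heritable
regime where the pipeline actually consumes the p-values.

## Curation and harmonization

Phecodes are canonicalized by stripping trailing decimal zeros ("250.20" ≡
"250.2") before computing depth.  A disease is kept iff case count ≥ 1000,
depth ≤ 1, category not in {symptoms, injuries & poisonings}, and not
manually excluded; drops record the first matching reason in that order.
Hierarchically duplicated codes cannot be removed algorithmically in
general, so the package takes a user exclusion list plus an optional
off-by-default heuristic (drop the deeper of a parent/child pair whose case
counts differ by < 10%).  Categories are configuration data (a
phecode→chapter map); the cardiometabolic set is the union of the
endocrine/metabolic and circulatory-system chapters.

Harmonization restricts all tables to (∩ᵢ variants) ∩ whitelist, removes
chr6:25–35 Mb (GRCh37 extended-MHC convention, configurable interval),
drops strand-ambiguous A/T and C/G variants, aligns alleles to the first
table's orientation (swaps negate beta and reflect eaf, preserving |z|;
strand complements are reconciled; irreconcilable pairs are dropped and
counted), and sorts by (chromosome, position, id).  The operation is
idempotent, and p-values of exactly 0 were already clamped to the smallest
positive float at read time.

## Synthetic studies

The generator draws per-variant z-score vectors across all P phenotypes from
the exact moment structure above: Σ_j = I + (l_j/M)·A with
A = diag(s)·R·diag(s), s_p = √(N_p h²_p), and R the planted phenotype
correlation matrix (unit diagonal, planted disease–biomarker r_g entries,
zero elsewhere; positive semi-definiteness is validated before sampling).
z is independent across variants — LD enters only through the LD scores,
which is precisely the regime LD-score regression assumes.  Consequences:
passing tests demonstrate correct recovery *of this model*, not robustness
to genotype-level LD, population stratification, case/control ascertainment,
or correlated biomarkers; those belong to the inputs, not the generator.

Key default choices (all configurable per scenario):

* **LD scores** Gamma(shape 6, mean 100) — right-skewed like real score
  distributions; mean and shape are stated in the scenario.
* **Panel ratio M = 500·m.**  The m simulated variants act as regression
  SNPs subsampled from a dense panel of M SNPs.  The ratio controls the
  per-variant non-centrality N·h²·l̄/M; 500 keeps it at a realistic,
  slightly conservative magnitude at the reference sizes (m = 5,000,
  N = 50,000, h² = 0.3) so that two *unrelated* heritable diseases share a
  chance genome-wide hit with probability ~3×10⁻⁵ per pair — this is what
  keeps planted direct-edge truth exact rather than approximate.
* **Direct-edge planting** boosts |z| above the genome-wide threshold
  (≥ 1.2×) at freshly drawn MAF-passing variants, disjoint across pairs and
  recorded in `truth.json`; planting is therefore independent of the
  correlation machinery, and boosted variants are excluded from estimator
  calibration claims.
* **Reference scenario**: 6 diseases (h² = 0.3, N = 50,000, realistic case
  counts and chapters), 5 biomarkers of which two carry disjoint planted
  cliques at |r_g| = 0.5 (signs mixed — the edge rule must ignore them) and
  three are null.  Null biomarkers emulate measurements that contribute no
  edges, and they keep the FDR's occasional false rejection on pairs with
  zero clique amplification.
* **Truth definition**: expected E is the planted shared-SNP pairs; expected
  E⁺ is the per-biomarker clique over diseases with planted |r_g| ≥ 0.3,
  the documented detectability bound (≈ 4–5× the asymptotic r_g SE at the
  reference sizes; planted correlations are at 0.5, well above it).
* **MAF** uniform on [0.0505, 0.5]; low-frequency variants (eaf = 0.01) are
  planted explicitly (`n_low_maf`, default 50 in the reference scenario) so
  the MAF filter is exercised deterministically.

Everything is driven by `numpy.random.default_rng` seeded from the scenario:
a fixed scenario yields a byte-identical fixture bundle.

## Numerical and interface choices

* Jackknife blocks: 200 by variant order; degenerate inputs (constant LD
  scores, more blocks than variants) are hard errors.
* Degree ranks use competition ("min") ranking; ties share the smallest
  rank.  Dense ranking is a one-line change in `competition_ranks`.
* Category-pair normalization divides by exposure: n_a·n_b off-diagonal,
  C(n_a, 2) on the diagonal; raw counts are always emitted alongside.
* Biomarker attribution is non-exclusive: an edge supported by two
  biomarkers credits both, so per biomarker new + redundant equals its total
  E⁺ memberships (asserted in tests).
* Cross-category fraction of an edgeless graph is undefined (NaN), not 0.
* In the focal-biomarker adjacency matrix the upper triangle codes
  none/direct/focal-indirect with direct taking precedence (the focal code
  marks edges that exist *because of* the biomarker); the lower triangle
  counts linking biomarkers per pair.
* Duplicate variant ids keep the first occurrence with a warning; duplicate
  (disease, trait) estimates are hard errors.
* Problem sizes in the test suite and acceptance script (5,000-variant
  panels, 100–200 replicates, 10–20 scenarios) were chosen as the smallest
  sizes at which the estimators are comfortably in their asymptotic regime.

## Limitations

* A full biobank-scale network (hundreds of curated diseases, dozens of
  biomarkers, ~1.2M whitelisted SNPs) requires the source PheWAS summary
  statistics plus non-algorithmic manual curation of hierarchically related
  phecodes, neither of which ships with the package; correctness is instead
  validated on planted-truth synthetic studies, whose guarantees are scoped
  by the generator's assumptions above.
* LD-score regression variants beyond the basic model (constrained
  intercept, partitioned heritability, liability-scale h²) are out of
  scope, as are LD-score computation, genome-build liftover, LD clumping of
  shared SNPs, and any causal (Mendelian-randomization) interpretation of
  the indirect edges.
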