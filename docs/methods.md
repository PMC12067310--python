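# Methods

## The measurement model and why normalization is needed

In a two-member co-culture, the LFQ intensity of protein *g* of strain *k*
in sample *s* is, to first order,

    I_gs ∝ f_ks · a_gc(s) · ε_gs

where `f_ks` is the cell fraction of strain *k* in sample *s*, `a_gc` the
per-cell abundance of the protein under condition `c(s)`, and `ε_gs`
multiplicative noise. A change in `f_ks` between conditions enters every
protein of the strain as a common log2 offset `Δlog2 f`, which a per-protein
differential test cannot distinguish from regulation. LFQRatio divides each
intensity by the summed intensity of all proteins assigned to the same strain
in the same sample; since the strain total carries the same `f_ks` factor,
the fraction is composition-free up to the (second-order) change in the
within-strain abundance composition.

Assumptions: the per-strain total per cell is approximately condition-
invariant (i.e., regulation affects a small share of total protein mass);
protein groups can be attributed to one strain; and MaxLFQ has already
handled between-run intensity calibration. When a large fraction of a
strain's proteome is regulated in one direction, the normalization absorbs
part of that signal — an intrinsic limitation of any sum-based scaling.

## Strain assignment and filtering

Groups are filtered before anything else: reverse (decoy) hits, potential
contaminants, site-only identifications, and groups with fewer than
`min_peptides = 2` peptides (the `use_unique` variant counts unique peptides
and is meant for proteome-size comparisons). Strain assignment then inspects
the majority-protein accessions: all in one strain → that strain; both
strains → `ambiguous`; any accession absent from the merged database →
`unknown` (hard error by default). Ambiguous groups are excluded from strain
totals and from the normalized output because their signal cannot be
attributed; their count is reported. Totals are computed after filtering, and
an `allow_unknown` switch tolerates database mismatches when exploring.

Per (strain, sample) the non-missing normalized values sum to the `scale`
constant to within 1e-9; `scale = 1` internally, while the CLI writes
MaxQuant-dialect output with `scale = 1e6` by default so downstream log2
values land in a familiar range. Scale cancels in fold changes.

## Physicochemical profiling

- **MW**: sum of average residue masses plus one water (18.0153 Da).
  Ambiguity codes X/B/Z have no mass; by default they raise an error, and a
  `skip` policy counts them as 0 Da with a warning.
- **GRAVY**: mean Kyte–Doolittle hydropathy over scored residues; unscored
  residues are excluded from the mean.
- **pI**: the unique zero of the Henderson–Hasselbalch net-charge sum
  (one N- and one C-terminus plus K/R/H and D/E/C/Y side chains), found by
  bisection on pH ∈ [0, 14] to a default bracket of 0.001 pH units. Net
  charge is strictly decreasing in pH, so no tie-breaking is needed.
- pKa values default to the EMBOSS set (N-term 8.6, C-term 3.6, K 10.8,
  R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1). All scales are fields of
  `PhyschemScales` and overridable, so other published sets (e.g.
  Bjellqvist) can reproduce other tools; the default is a declared
  convention, not a claim about any particular script.

## Digestion and shared peptides

Trypsin/P semantics (cleave after every K/R, proline does not block) match
the usual MaxQuant search setting; classical trypsin is available behind a
flag. Peptides with up to `missed_cleavages` internal sites are enumerated
with positions. The theoretical shared-peptide analysis digests both
proteomes, keeps peptides of 8–25 residues (the typically detectable range),
deduplicates within strain, and intersects by exact string equality —
I and L are kept distinct by default because search engines report them as
written; an `collapse_il` mode merges them for a conservative estimate.
The iBAQ divisor uses fully-cleaved peptides in the standard 6–30 residue
window, configurable independently of the shared-peptide window.

## Differential expression

Run per strain on that strain's (normalized) block:

1. **Consistency filter + log2.** Zeros are treated as missing throughout;
   a protein is kept if it has ≥ `min_valid_per_condition` (default 2)
   observed values in at least one condition. The rule is deliberately
   configurable since "consistently quantified" is a convention.
2. **Imputation.** Missing values are MNAR-dominated (censored low
   intensities), so each sample column's missing cells are drawn from
   Normal(μ − 1.8σ, (0.3σ)²) with μ, σ the column's observed moments.
   Columns with < 3 observed values fall back to matrix-wide moments with a
   warning. Imputation is done once, before model fitting, and is
   deterministic given the seed; `imputation="none"` gives complete-case
   analysis.
3. **Moderated t.** Ordinary two-group fits give the mean difference (log2
   fold change) and pooled variance s_g² on d = n₁+n₂−2 df. The variances
   are shrunk toward a scaled-F prior with hyperparameters (d₀, s₀²)
   estimated by moment matching on log s_g² (digamma/trigamma relations;
   the trigamma inverse is found by bracket expansion + Brent's method at
   1e-8 tolerance). Posterior variance s̃² = (d₀s₀² + d s²)/(d₀ + d);
   t = Δ/(s̃·√(1/n₁+1/n₂)) on d₀ + d df. If the moment equation has no
   positive solution (log-variances no more dispersed than χ² noise), d₀ is
   +∞ and all variances shrink fully to s₀² — the limiting behavior rather
   than a failure. d₀ = 0 reproduces the ordinary pooled t exactly (tested),
   and the whole fit is cross-checked against Bioconductor limma in the
   suite. Zero sample variances are excluded from hyperparameter
   estimation but still receive a posterior variance.
4. **FDR + calling.** Benjamini–Hochberg step-up adjustment; significance
   requires adjusted p ≤ 0.05 **and** |log2 FC| ≥ 1, both inclusive at the
   boundary.

## Synthetic data

The generator emulates exactly the structure the method assumes: proteins
are concatenations of tryptic segments (interior residues exclude K/R, each
segment ends in K/R, lengths 8–25), so digestion behaves like a real
proteome's detectable fraction; a configured fraction of strain-B proteins
receives one exact strain-A tryptic peptide at a cleavage boundary.
Intensities follow the measurement model above on log2 scale: per-cell log2
abundance uniform over a four-decade range (log10 intensity 6–10), plus
log2(cell fraction), plus Normal(0, 0.3) residual noise — a residual SD
typical of well-behaved LFQ replicates. MNAR censors each sample's lowest
5% of intensities; MAR drops a further 2% at random; both masks are recorded
as ground truth. Defaults describe the headline scenario (1,000 proteins per
strain, strain-A fraction 0.8 → 0.2, three replicates, no true DE); planted
effects add ±2 log2 units to chosen proteins in all non-reference
conditions. Six rows that default filtering must remove (2 reverse, 2
contaminants, 2 single-peptide) are always injected with MaxQuant-style
`REV__`/`CON__` prefixes.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide bookkeeping (peptide counts are drawn, not derived), retention
time and ionization efficiency effects, correlated replicate structure,
between-protein abundance correlation, and search-engine identification
error. Passing tests therefore validate the normalization and inference
machinery under the stated model, not MaxQuant itself.

Problem sizes in tests are chosen for statistical resolution at interactive
runtimes: 1,000–5,000 proteins for calibration/recovery checks, 100–1,000
random cases for oracle equivalences, 100,000 draws for imputation moments.

## Numerical choices

- Missing = 0 on disk (MaxQuant dialect), NaN in memory; NaN never enters
  totals, means, or log transforms.
- Intensities written with `%.10g` so normalized fractions survive a
  round trip.
- Seeds: all stochastic steps take explicit seeds; derived generator
  streams use `default_rng([seed, k])` so the FASTA and quant stages are
  independently reproducible.
- Bisection: 50 iterations max; BH implemented as a vectorized reverse
  cumulative minimum.

## Known limitations

- Two strains only; the equation generalizes to more, the validation here
  does not.
- Two-group contrasts; no multi-factor designs or batch terms.
- No inter-sample median/quantile normalization (assumed done by MaxLFQ).
- Localized (non-English) MaxQuant column names are not recognized.
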