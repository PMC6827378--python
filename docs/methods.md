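# Methods

## Scope and data model

The package quantifies serine-for-proline misincorporation at the level of
*detections*: its inputs are post-search peptide-spectrum match (PSM)
tables, not spectra. Spectrum scoring, semi-supervised rescoring and
raw-file processing are out of scope; any search engine's export can be
adapted to the PSM TSV interchange format (columns `spectrum_id`,
`replicate_id`, `base_seq`, `mods`, `observed_mass`, `score`, `is_decoy`).
Scores are "higher is better"; e-value-based engines should negate or
log-transform on import.

A `ProteinRecord` couples a protein with its coding sequence and is
validated to translate exactly under the standard genetic code (a trailing
stop codon is accepted and stripped; internal stops are errors). This gives
every residue its encoding codon, the basis of codon-resolved estimates.
CDS input is accepted in DNA or RNA alphabet; codons are reported in RNA
(CCA/CCG/CCU/CCC) by default. Residue indices are 0-based internally and
1-based in every exported table.

## Digestion and the peptide index

LysC cleaves C-terminal to every lysine, including K-P bonds — there is no
proline rule for LysC, which also maximizes the yield of proline-containing
peptides. Digestion products merge up to `max_missed = 2` adjacent
fragments and are filtered to 6–50 residues by default; the bounds are
ordinary search-engine practice, are configurable, and can be disabled
(`min_len=1, max_len=None`). N-terminal methionine clipping is not
performed, keeping the residue→codon map trivial. A peptide sequence is
*unique* when it maps to exactly one proteome locus; only unique peptides
enter the frequency estimates, because codon assignment is otherwise
ill-defined.

## Masses, decoys and FDR

Neutral monoisotopic masses are used throughout (identification-level
artifact; charge states are out of scope). Residue and formula masses come
from pyteomics; the substitution is carried as a variable modification with
delta m(Ser) − m(Pro) = −10.02073 Da, so mass arithmetic is additive to
numerical precision. PSMs are checked against the theoretical modified mass
at 50 ppm on import and failures are dropped with a logged count.

Decoys are full protein reversals (one per target, `decoy_` prefix; the CDS
is reversed codon-wise so decoy records still satisfy the translation
invariant). The FDR estimate at score s is #decoys(≥ s) / max(1,
#targets(≥ s)) without the +1 correction; tied target/decoy scores are
counted decoys-first (conservative). Q-values are the running minimum of
FDR over decreasing score, and the default cut is q ≤ 0.01. A small
selection bias of the realized false-discovery proportion is inherent to
threshold competition; at the survivor counts used in the calibration test
(≈5,000 per run) it is an order of magnitude below binomial noise.

## Substitution calling and the frequency estimator

Candidates are filtered PSMs carrying 1–2 Pro→Ser modifications (at most
two per PSM, mirroring the search configuration). A candidate fails with

- `extra_modification` — it carries oxidation or N-terminal acetylation
  (carbamidomethyl-C, being fixed, never fails a candidate);
- `no_wildtype_counterpart` — no base detection of the same peptide exists
  in the same replicate. Base detections in *any* modification state count:
  the stringency filter is defined on substituted peptides only, and an
  oxidized wild-type detection is still evidence the peptide was present;
- `ambiguous_mapping` — the substituted sequence equals a wild-type peptide
  somewhere in the proteome. Such calls are unverifiable (the spectrum may
  simply be that other peptide) and are excluded by default; the filter can
  be disabled (`--no-ambiguity-filter`) and failures are reported with
  reasons rather than discarded silently.

The denominator of the overall estimate is the number of distinct unique
proline-containing peptides with a base detection in the replicate; the
numerator is the subset with at least one passing substituted detection. A
zero denominator yields an undefined (not zero) estimate. Per-codon
estimates restrict the denominator to peptides with exactly one proline —
multi-proline peptides are excluded from every codon class to avoid
site-localization ambiguity, which is why per-codon denominators sum to
less than the overall denominator. Frequencies are computed per replicate;
strain comparisons use Welch's t-test on replicate frequencies (t and the
Welch–Satterthwaite df via scipy).

## Growth curves and reporter folds

Growth is modelled with the three-parameter logistic
N(t) = K / (1 + ((K − N0)/N0) e^(−rt)), the model underlying standard
microplate doubling-time tools, with t_d = ln 2 / r. Fits are least-squares
(`scipy.optimize.curve_fit`) with positivity bounds, initialized from the
plateau (K), the first reading (N0) and the log-OD slope over the first
quartile of points (r). Curves with no net growth, or fits that do not
converge, return `converged=False` with diagnostics instead of raising.
Background subtraction is not applied by default (an optional blank can be
subtracted upstream). Reported folds are rounded to one decimal to match
the usual reporting convention; raw values are always emitted alongside.

Heat-shock induction is the ratio of mean density-normalized fluorescence
readings (variant over reference), and the colony-size assay is the ratio
of means with a Welch test; both are invariant to common rescaling of the
readings.

## The cloverleaf annotation

The packaged annotation of the serine tRNA with a UGG anticodon is
*hand-encoded* (not a database extract): one row per Sprinzl-style position
(`label`, `base`, `element`, `partner`; an optional `modified` column is
accepted) with insertions ("20a"/"20b") and extended-variable-arm labels
("e11"…"e23") preserved. Validation enforces symmetric pairing, paired
positions only inside stem elements, and wild-type pairs that are
Watson-Crick or G:U (the T-stem 51:63 pair is a wild-type U:G wobble).
Positions 8, 9, 26, 44, 48 and the discriminator 73 are single-stranded
linkers; the variable-arm stem pairs 45:e21, e11:e22 and e12:e23, so
position 45 is paired while 44 and 48 are not — the assignment that makes
the tabulated mutation set classify as observed (G45A and Ge23A then sit at
the two ends of the variable-arm stem, and both abolish their pair).

Classification of a point mutation is a total function: loop/linker →
`single_stranded`; at a paired position, the mutated pair {alt, partner}
is `creates_GU` if it is {G,U}, `other_stem` if it is still Watson-Crick
(or G:U from a wobble), and `abolishes_pair` otherwise.

## Synthetic-data generators

The generators emulate the study design: biological triplicates, a
proteome of ~500 proteins (i.i.d. residues at yeast-like composition,
CCA-heavy proline codon usage), peptide detection probability 0.3,
identification error 1% (matching the FDR operating point), and growth
curves on a 15-minute grid over 24 h (97 points) with additive Gaussian OD
noise (sd 0.01).

Substitution is modelled at the detection level: each detected
proline-containing peptide yields a substituted PSM per proline site with
the probability p_c of that site's codon (one substitution per emitted
PSM; the data model and validation support the search's two-per-peptide
cap). Under this model the frequency statistic is an unbiased estimator of
p_c by construction. The mapping from molecular substitution rates to
detection probabilities — ionization efficiency, abundance, spectral
quality — is deliberately not modelled, so passing round-trip tests
demonstrates correctness of the *estimator*, not instrument-level realism.
Configurable corruption rates exercise the stringent filters (extra
modifications on substituted PSMs; withheld base PSMs); these are switched
off in estimator-recovery experiments because each removes true events by
design and is tested separately. Score distributions default to two
Gaussians (correct: mean 4, sd 1; incorrect/decoy: mean 0, sd 1) —
sufficient to exercise target-decoy competition, with no claim of spectral
realism. False-target and decoy counts are drawn from the same binomial
distribution so decoys are a faithful stand-in for false targets.

All outputs are pure functions of (config, seed): per-stage generators are
spawned from one seed sequence, and TSV floats are written with pinned
formatting, so identical configs give byte-identical files.

## Experiment sizes used in the acceptance tests

Chosen as desk-scale renditions of the study design: estimator recovery
uses 500-protein proteomes, 4 strains whose per-codon rates span
0.003–0.05, 3 replicates and 20 seeds (~1 minute); FDR calibration uses
5,000 correct / 500 incorrect / 500 decoy PSMs per seed for 20 seeds, a
size at which threshold-selection bias (~1e-4) is well below binomial
error; null-data runs use 200-protein proteomes and 20 seeds. Statistical
assertions use 3-standard-error bands of the experiment actually run.

## Known limitations

- Only Pro→Ser substitution is searched; the data model permits other
  substitutions but v1 does not enumerate them.
- No site-localization scoring: multi-proline peptides are simply excluded
  from codon-level estimates rather than localized.
- No protein-level FDR, no intensity-based (quantitative) error rates.
- The denominator counts peptides detected as wild-type in any
  modification state; counting only unmodified detections would shrink
  denominators slightly (config-selectable readings were considered and
  the "any state" reading adopted as the one consistent with the
  counterpart filter).
- The cloverleaf fixture is a curated encoding, adequate for structural
  classification; it is not a substitute for an experimentally derived
  secondary structure, and other tRNAs can be supplied in the same TSV
  format.
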