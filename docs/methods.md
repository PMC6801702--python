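# Methods

## Scope

`cathmap` models how endolysosomal cysteine cathepsins (S, L, B) fragment
protein antigens, and provides the analysis chain needed to confront such
models with mass-spectrometry digest data: octamer encoding, per-dipeptide
neural-net ensembles, peptide-to-cleavage-event mapping, the validation
statistics, and immunoglobulin variable-region profiling in CDR3-relative
coordinates. Everything runs against synthetic ground truth generated by
the package itself, so each stage is testable without external data.

## Cleavage-site octamers and encoding

The substrate context a papain-family protease reads is taken to be the
eight residues P4 P3 P2 P1 | P1′ P2′ P3′ P4′ around the scissile bond; the
bond is hydrolyzed between window positions 4 and 5. A substrate of length
L has L − 7 such full windows, with the P1 index running 4 … L − 4.
Coordinates are 1-based throughout and cleavage positions are reported as
P1′, the first residue after the cut.

Residues are represented by their scores on the first three principal
components of a standardized physicochemical property table. The bundled
table collects ten published indices (Kyte–Doolittle hydropathy,
Hopp–Woods hydrophilicity, residue mass, Zamyatnin volume, Grantham
polarity, pI, net charge, Zimmerman bulkiness, Chou–Fasman helix and sheet
propensities); its three components capture 84% of the property variance.
Any user table with the same layout can be substituted, and the table's
SHA-256 hash travels with every trained model so that a model can never be
silently applied with a different encoding. Component signs are fixed by
making each component's largest-magnitude loading positive, which makes
scores identical across linear-algebra backends.

Design choices at the boundaries: octamers truncated by the chain termini
are *not* enumerated — inventing padding residues would fabricate
physicochemical context — so the first four and last three bonds of a
chain are never scored (a documented blind spot). Windows containing
non-canonical letters (X, U, B, Z) are skipped, because no property values
exist for them.

## Per-dipeptide ensembles

Protease specificity is dominated by the P1-P1′ pair, so training examples
are partitioned by that dipeptide (≤ 400 partitions) and each partition
gets its own ensemble of feed-forward networks (one hidden layer of 6 tanh
units, logistic output) over the 24 encoded features. The ensemble
prediction is the arithmetic mean of its members; each of the 10 members
is trained on a stratified bootstrap resample with its own deterministic
seed, derived stably from the dipeptide letters so results do not depend
on dictionary order.

Three numerical choices matter:

* **Regularization.** The L2 penalty defaults to `alpha = 5.0`. Partitions
  hold tens of binary examples against 24 inputs; with weak shrinkage,
  full-batch lbfgs converges to saturated, near-separating solutions whose
  outputs rank badly across dipeptides. Heavy shrinkage keeps member
  outputs calibrated; held-out rank recovery roughly doubles relative to a
  near-unregularized fit. All architecture values are constructor
  parameters.
* **Class imbalance.** Surviving (negative) bonds vastly outnumber cut
  bonds, so negatives are down-sampled to at most 5× the positives before
  network training. Because that changes the class prior, ensemble outputs
  are corrected back at prediction time by multiplying the odds by the
  kept-negative fraction. Constant-rate estimates are always computed from
  the *full* partition, never the down-sampled one.
* **Sparse partitions.** A partition with fewer than 10 examples of either
  class cannot support a network; it falls back to a Laplace-smoothed
  constant rate (n⁺ + 1)/(n + 2), flagged `degenerate` when a class is
  absent entirely. Bonds whose dipeptide was never seen receive the global
  smoothed prevalence and a `fallback` flag.

Models serialize to JSON (weights, config, seeds, encoding hash).
Prediction from a serialized model uses an explicit tanh/logistic forward
pass, which tests verify is the exact function of the fitted sklearn
network.

Training labels can be built from a peptide-library digest: a bond is
positive when it coincides with an observed peptide terminus interior to
the protein, negative when it lies strictly interior to an observed
peptide; a bond seen both ways is positive, since one observed cut proves
cleavability. Chain termini are never cleavage evidence.

## Digest mapping

A detected peptide spanning [start, end] of a substrate of length L
testifies to an amino-end cut at P1′ = start (if start > 1) and a
carboxy-end cut at P1′ = end + 1 (if end < L); an internal peptide thus
yields exactly two events, a terminal peptide one, the intact chain none.
Identical sequences within one (sample, substrate, time, pH) condition are
counted once; across samples they add. Peptides matching a substrate at
several positions keep their annotated span but are marked `ambiguous`.
Peptides also present in a no-enzyme control for the same substrate and
time are excluded (toggleable). An optional flag treats the isobaric
residues I and L as equivalent during location.

## Validation statistics

Counts are compared to predictions through intra-substrate
z-standardization: within each (substrate, cathepsin, time, pH) stratum
every enumerable full-window bond enters — unobserved bonds as zeros — and
counts are scaled to mean 0, sample SD 1. Zero-variance strata are flagged
and excluded downstream. Including the zeros is essential: the contrast of
interest is precisely between low-probability bins (mostly uncut) and
high-probability bins.

Predictions are grouped into five fixed bins, rendered as the conventional
labels 0–0.19, 0.2–0.39, 0.4–0.59, 0.6–0.79, 0.8–1. These are half-open
0.2-wide intervals with the top bin closed; probabilities are binned at
full precision, the 2-dp labels being display renderings only.

Per-bin z-score samples are compared with Welch's heteroscedastic one-way
ANOVA (Welch–Satterthwaite denominator df, implemented in closed form and
cross-checked against `pingouin`), followed by Tukey–Kramer pairwise
comparisons (via `statsmodels`) with a compact letter display assigned by
insert-and-absorb. One subtlety: Welch's F equals the classical one-way F
*exactly* only for two groups of equal size and variance; for k > 2 the
denominator correction 1 + 2λ(k−2)/3 exceeds 1 even under exact
homoscedasticity, so the classical-equivalence check is stated at k = 2.
No multiplicity correction is applied across cathepsins; each enzyme is an
independent analysis.

Auxiliary summaries: the fraction of sites above a probability threshold
carrying at least one observed event (coverage); peptide-length fractions
in HLA-relevant windows, with class II fixed at 11–20 inclusive and class I
defaulting to 8–11 as a configurable convention (the class I window is a
convention of this package, not a literature constant); the signed residue
offset from each observed event to the nearest high-probability (> 0.8)
site, with ties resolved toward the N-terminal side — a left-shifted
distribution is the signature of carboxypeptidase shaving, as seen for
cathepsin B. Raw signed offsets are reported; any normalization by
substrate length is left to the caller. Sample quality control uses Ward
minimum-variance clustering of peptide incidence vectors (scipy linkage),
with rows pre-sorted lexicographically by sample id for determinism.

## Immunoglobulin profiling

Variable regions differ in length, but the cysteine opening CDR3 is
conserved, so positions are re-indexed as (absolute − cdr3_cys), putting
the anchor at 0; constant regions are displayed from offset 30 so both
region types share an axis. Family labels and the CDR3 cysteine index are
*inputs* (IMGT-style annotation); a heuristic helper (last Cys before a
J-region motif) exists but is flagged non-authoritative. Family mean
profiles average predicted probabilities per relative position over the
records covering it, reporting n; positions covered by no record are
absent, never zero-filled. Sequences of different framework lengths are
combined at their raw offsets, without gap alignment — positions far from
the anchor therefore mix non-homologous residues, a documented limitation.
Eluted peptides are overlaid in the same coordinates with flags recording
whether each terminus coincides with a predicted site above threshold
(termini at chain ends are not applicable). An epitope span is called
destroyed when at least one predicted site at or above the threshold
(default 0.5, configurable) lies strictly interior to it, i.e. P1′ in
[start + 1, end]; a cut at P1′ = start merely releases the epitope's own
N-terminus.

## Synthetic ground truth

The generator defines the study conditions under which the pipeline is
exercised:

* **Rule.** Each dipeptide carries a logistic model over the 24 encoded
  features. Intercepts scatter around logit(0.15) with SD 1.5 — a marginal
  cleavage propensity of ~15% with strong dipeptide preferences — and 25%
  of dipeptides carry context weights of SD 0.06 each (total context
  contribution ≈ 0.5 logit units). This encodes the field's understanding
  that P1/P1′ identity dominates specificity with flanking positions as
  moderate modifiers; with context much stronger than this, no method
  could recover it from a library of realistic size, and with none, the
  ensembles would have nothing to learn beyond rates.
* **Library.** 50 random proteins of 300 residues (uniform composition,
  keeping all dipeptide partitions populated), every full-window bond
  labeled by a Bernoulli draw at its rule probability — about 14,650
  examples, or ~37 per dipeptide, mirroring the sparsity a
  proteome-derived peptide library produces per partition.
* **Digest.** Each bond carries an independent exponential cut hazard
  `hazard_scale × p_bond` per hour, so cut sets are nested over the 6/24/30 h
  time course and the intact-bond survival curve is exponential. The
  default hazard 0.02/h makes a 300-residue substrate show substantial
  fragmentation at 6 h and a growing detected pool through 30 h. Fragments
  are maximal uncut stretches; only fragments of 6–40 residues appear in
  the peptide table, emulating the nLC-MS detection window. Released
  fragments are not re-cut beyond the sampled bond set (single-pass
  kinetics), and fragment identification is perfect within the window — no
  missed identifications, intensity effects, modifications or I/L
  confusion. Passing tests therefore demonstrate correctness of the
  analysis chain under ideal detection, not robustness to real MS noise.
* **Ig-like records.** Families share fixed random frameworks; CDR loops
  are randomized per record and the residue before CDR3 is forced to
  cysteine. These are labelled synthetic and are not germline IGHV genes.

Every simulation writes a truth ledger (cut times, fragment tilings,
detection outcomes). Tests reach observations only through the public
peptide table and use the ledger solely as the expected answer.

## Problem sizes and reproducibility

The bundled end-to-end checks use the library size above, 10 held-out
300-residue substrates for rank recovery, three replicate digests of
12 × 300-residue substrates for the binned pattern, and 200 substrates for
the mapping recount — sizes at which the whole suite completes in well
under a minute of compute while leaving the stochastic checks comfortable
margins. All randomness flows from explicit integer seeds; per-dipeptide
and per-member seeds are derived arithmetically from the base seed, so
identical seeds reproduce models, simulations and TSV outputs
byte-for-byte.

## Known limitations

* The original platform's property set and PCA basis are not public;
  encodings here are internally consistent but not numerically equivalent
  to the authors'.
* Bonds within 4 residues of a terminus are never scored or cut in
  simulation (no-padding policy).
* Cathepsin B's carboxypeptidase mode violates the endopeptidase
  assumptions of both the octamer model and the single-pass digest
  kinetics; the distance-to-site summary detects its signature but the
  generator does not emulate it.
* Family mean profiles average raw CDR3-relative offsets without gap
  alignment across framework-length variants.
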