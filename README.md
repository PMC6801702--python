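# cathmap

Prediction and mass-spectrometry validation of cathepsin cleavage sites in
protein antigens.

Endolysosomal cysteine cathepsins (S, L, B) fragment internalized antigens
— CNS autoantigens, therapeutic monoclonal antibodies, the B-cell
receptor itself — into the peptides that HLA class II presents to CD4⁺
T cells. Where a cathepsin cuts therefore shapes which epitopes survive
processing. `cathmap` is a toolkit for researchers in antigen processing
and degradomics that covers the full analysis loop:

* **Predict.** A substrate is decomposed into cleavage-site octamers
  (CSOs), the windows P4P3P2P1–P1′P2′P3′P4′ around each peptide bond. Each
  residue is encoded by its scores on the first three principal components
  of a standardized amino-acid physicochemical property table, so an
  octamer becomes 24 numbers. Training examples are partitioned by their
  P1-P1′ scissile dipeptide (up to 400 partitions) and each partition gets
  its own ensemble of small tanh neural networks; the mean member output
  is the cleavage probability in [0, 1] for that bond.
* **Map.** MS-identified digest peptides (MaxQuant `peptides.txt`-style
  tables) are converted into per-bond cleavage events: a peptide spanning
  [start, end] evidences cuts at P1′ = start and P1′ = end + 1, chain
  termini excluded.
* **Validate.** Observed per-bond counts are z-standardized within each
  substrate (unobserved bonds entering as zeros), grouped into five
  prediction-probability bins (0–0.19 … 0.8–1), and compared by Welch
  ANOVA with Tukey–Kramer letters; coverage fractions, HLA length windows,
  distance-to-predicted-site curves and Ward sample clustering round out
  the report.
* **Profile immunoglobulins.** Variable-region positions are re-indexed
  relative to the conserved CDR3-opening cysteine (position 0; constant
  regions display from 30), enabling IGHV family mean cleavage profiles,
  overlay of HLA-eluted peptides, and epitope-integrity calls.
* **Simulate.** A synthetic-data module plants per-dipeptide logistic
  cleavage rules, draws training libraries, and simulates time-course
  digests with exponential per-bond cut hazards and a 6–40-residue
  detection window, writing both a peptide table and a ground-truth
  ledger — so every stage above is testable with a known answer.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Train on a synthetic peptide library, simulate a digest from the same
planted rule, and ask whether observed cuts track predicted probability:

```python
import pandas as pd
import cathmap as cm

rule = cm.make_rule(seed=0)                       # planted specificity
examples, truth, _ = cm.generate_training_library(
    rule, n_proteins=50, protein_length=300, seed=0)
model = cm.DipeptideEnsembleClassifier(random_state=0)
model.fit(examples, [ex.label for ex in examples])

config = cm.SyntheticDigestConfig(n_substrates=4, substrate_length=300, seed=1)
peptides, ledger = cm.simulate_digest(config, rule)
substrates = peptides.attrs["substrates"]

events = cm.accumulate_events(peptides[peptides.time_h == 24.0], substrates)
bonds = {sid: cm.cso_positions(s) for sid, s in substrates.items()}
zs = cm.z_standardize(events, bonds)
profile = pd.concat([model.predict_profile(s, sid)
                     for sid, s in substrates.items()], ignore_index=True)

comp = cm.binned_comparison(profile, zs)
for label, mean in comp["bin_means"].items():
    print(f"  {label:>9}: {mean:+.3f}")
w = comp["welch"]
print(f"Welch ANOVA: F={w['F']:.1f}, df=({w['df1']:.0f}, {w['df2']:.1f}), "
      f"p={w['p']:.2e}")
print(comp["tukey"][["group", "n", "mean", "letters"]].to_string(index=False))
```

prints

```
     0-0.19: -0.200
   0.2-0.39: -0.038
   0.4-0.59: +0.250
   0.6-0.79: +0.717
      0.8-1: +1.193
Welch ANOVA: F=21.0, df=(4, 188.3), p=2.53e-14
   group   n      mean letters
  0-0.19 751 -0.199966       A
0.2-0.39 190 -0.037508      AB
0.4-0.59  85  0.250012       B
0.6-0.79  80  0.716651       C
   0.8-1  66  1.192691       D
```

The mean standardized cut count rises monotonically across the five
probability bins — bonds the model calls likely to be cleaved are indeed
cut more often — the Welch ANOVA rejects equality of bins decisively, and
the letter display shows the low- and high-probability bins are cleanly
separated. Most bonds sit in the lowest bin, as expected when only a
minority of dipeptide contexts suit the enzyme.

The same workflow is available from the shell:

```bash
cathmap simulate --seed 4 --out sim/
cathmap map --peptides sim/peptides.txt --fasta sim/substrates.fasta --out events.tsv
cathmap train --labels labels.tsv --seed 4 --out model.json
cathmap predict --fasta sim/substrates.fasta --model model.json --out profile.tsv
cathmap validate --profile profile.tsv --events events.tsv \
    --fasta sim/substrates.fasta --out report/
```

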