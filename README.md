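# scmpep

An interpretable scoring-card classifier for tumor-homing peptides (THPs) —
short peptides (3–30 residues) that selectively recognize tumor cells or
tumor vasculature and are of interest as drug-delivery vehicles.

Black-box sequence classifiers predict but do not explain. The scoring card
method (SCM) instead assigns each of the 20 standard amino acids a
*propensity score* `APS_i` on a 0–1000 scale, scores a peptide `P` of length
`L` by the composition-weighted sum

```
S(P) = Σ_i aa_i · APS_i = (1/L) Σ_positions APS(residue)
```

where `aa_i` is the occurrence frequency (count/length) of residue `i`, and
calls `P` positive iff `S(P) > Cutoff`. The card itself is the model: its
ranking of residues is directly readable biology (for THPs, cysteine and
tryptophan at the top; isoleucine and lysine at the bottom).

Cards are estimated in two stages:

1. **Initial card** — per-residue ratio of mean positive-class to mean
   negative-class composition, min–max rescaled to [0, 1000].
2. **GA refinement** — a genetic algorithm perturbs the card to maximize
   `Fit = w1·AUC + w2·R` (defaults `w1 = 0.9`, `w2 = 0.1`), where AUC is the
   cross-validated area under the ROC curve of the weighted-sum scorer and
   `R` is the Pearson correlation of the candidate with the initial card —
   the second term keeps the optimized card interpretable as a composition
   propensity.

The package also characterizes a fitted card by correlating its 20 scores
with AAIndex1 physicochemical property scales (candidates: `r > 0.5`), and
computes the reproducible physicochemical columns of the published benchmark
tables (280 nm extinction coefficient, integer net charge, molecular
weight).

## Worked example

Scoring two benchmark peptides with the bundled published card
(cutoff 301):

```python
>>> from scmpep import load_reference_card, score_peptide
>>> card = load_reference_card()
>>> sp = score_peptide("CFWPNRC", card)
>>> sp.raw_score, sp.rounded_score, sp.prediction
(683.5714285714284, 684, 1)
>>> score_peptide("IKIQD", card).rounded_score
69
```

`CFWPNRC` averages the propensities of its residues
((2·1000 + 424 + 981 + 587 + 195 + 598)/7 = 683.57 → 684), well above the
cutoff of 301, so it is called a THP (prediction 1); `IKIQD` scores 69 and
is called non-THP.

Training on synthetic composition-biased data (positives enriched in
C/W/R, negatives in I/K/V):

```python
>>> from scmpep import PropensityScoreModel, SynthSpec, generate
>>> model = PropensityScoreModel(generate(SynthSpec(seed=0)))
>>> res = model.fit(generations=40, seed=1)
>>> print(res.summary())
Propensity score card (scoring-card method)
===============================================
n peptides: 980 (490 pos / 490 neg)
GA: pop=50 gen=40 seed=1
fitness (w1*AUC + w2*R): initial=0.9911 optimized=0.9928
selected cutoff: 345
...
10-fold CV: ACC=0.961 Sn=0.939 Sp=0.984 MCC=0.923 AUC=0.993
```

The fitted card ranks the planted enriched residues (W 970, C 897, R 768)
far above the depleted ones (I/K/V ≈ 0), and the 10-fold cross-validated
metrics confirm near-perfect separation at the selected cutoff.

The same workflows are available from the shell:

```
scmpep train positives.fasta negatives.fasta --out card.tsv
scmpep predict card.tsv query.fasta
scmpep evaluate card.tsv pos.fasta neg.fasta
scmpep pcp card.tsv --min-r 0.5
scmpep synth --outdir data/ --bias 8
scmpep reference --outdir reference/
```

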