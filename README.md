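# mu8

Quantify and localize how a reference protein deviates from its family of
homologs across amino-acid biophysical characteristics — accounting for
family conservation and for 3D Cα proximity — and export the result as a
visualization-ready JSON bundle.

The intended user has a multiple sequence alignment containing a suspect
(often dysfunctional) protein together with many functional relatives, a PDB
structure of one functional family member, and a set of amino-acid index
scales (AAindex1 format). The question is: *which residues of the reference
behave most unlike the family, in what biophysical respect, how conserved
are those positions, and what do they sit next to in the fold?*

## The statistic

For characteristic *p* (an amino-acid index scale, or the first principal
component of a class of scales) and cropped reference position *r*:

```
cs(p, r) = ( is_ref(p, r) − mean_fam(p, r) ) / σ_fam(p, r)
```

`is_ref(p, r)` is the value of *p* for the reference residue at *r*;
mean and σ (population form) are taken over the family's residues in the
same alignment column. The score is a conservation-weighted deviation:
property changes in conserved columns (small σ) are amplified. Perfectly
conserved columns (σ = 0) use a floored denominator — 1% of the median
positive σ — so they rank highest without producing infinities; floored
cells are flagged. By default each of the six characteristic classes
(alpha/turn propensity, beta propensity, hydrophobicity, composition,
physicochemical, other) is represented by the first principal component of
its standardized member scales, with the explained-variance share reported.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

Generate a synthetic study — a 248-residue reference in a family of 200
homologs, with a 7-residue anomalous region implanted at positions 150–156
— and run the full pipeline:

```
mu8 simulate --seed 7 --outdir demo/
mu8 run --msa demo/family.afa --ref-id REF \
        --aaindex demo/scales.aaindex1 --classes demo/classes.tsv \
        --pdb demo/structure.pdb --focus 150:156 \
        --out demo/bundle.json --plot demo/overview.png
```

Ranking positions by summed |c| over the six characteristics (what the
stacked-bar view shows) puts every implanted position in the top ten:

```
top10: [64, 72, 132, 150, 151, 152, 153, 154, 155, 156]
```

At position 150 (residue R in this simulation) the per-characteristic
c-scores read, e.g.:

```
 + beta_propensity   +4.96
 + physicochemical   +4.51
 + hydrophobicity    +2.85
 - alpha_turn        -0.65
```

i.e. the implanted residue is ~5 family standard deviations more
beta-prone than the family consensus at that position. With the focus set
to 150:156 and the default 0–8 Å band, the proximity chords bundle to two
arches flanking the focus:

```
chords: (145–149, min 3.80 Å)  (157–164, min 3.55 Å)
```

each chord connecting the focus to a maximal run of consecutive residues
within the band, darkest chord = closest. `demo/bundle.json` contains the
histograms (40 bins on ±3σ with clamped-tail counts), the per-position
stacked scores, the per-characteristic conservation rows, the chords and
the proximity histogram; `demo/overview.png` is a static rendition. The
bundle validates against `src/mu8/data/vizbundle.schema.json`.

The same steps are available as library calls (`mu8.synth_family`,
`mu8.score_alignment`, `mu8.export_viz_bundle`, ...) — the CLI is a thin
wrapper.

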