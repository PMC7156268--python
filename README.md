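# adhesiometry

Quantification pipelines for yeast cell–cell adhesion experiments, for
groups studying adhesin-mediated kin discrimination and biofilm
competition. The package turns three kinds of raw measurement into
comparable numbers, with a shared statistical layer and fully seeded
synthetic-data generators so every stage is testable without microscope
or AFM access:

- **Aggregate-size microscopy** (plate scans of spread cell suspensions):
  background-corrected global-threshold segmentation with watershed
  dissection, reporting the total area (mm²) covered by aggregates of
  each size class I–IV per cm² of imaged field.
- **Competitive-biofilm segregation** (paired RFP/GFP colony images):
  iterative-Otsu colony detection, autofluorescence/gain normalization,
  and the fraction of RFP-dominated pixels along a ring 50 px inside the
  colony edge and over the whole colony, with a superior/inferior
  dominance ratio binned into five categories.
- **Single-cell force spectroscopy** (force–distance curves): linear
  baseline/drift removal and extraction of the maximum adhesion force

      F_max = max(0, −min F_retract(s))   [nN, after baseline correction]

  plus per-group summaries and contact-time kinetics.
- **Statistics**: Welch's unpaired t-test, Wilcoxon rank-sum (exact by
  enumeration for n₁+n₂ ≤ 12, tie-corrected normal approximation
  otherwise), Spearman rank correlation (exact permutation p for n ≤ 7),
  the significance-star convention (p > 0.05 n.s; 0.05 ≥ p > 0.01 `*`;
  0.01 ≥ p > 0.001 `**`; p ≤ 0.001 `***`), and the cross-assay report
  correlating single-cell F_max with population aggregate area.

See `docs/methods.md` for the model conventions, defaults and known
limitations.

## Worked example

Simulate a competitive biofilm whose expanding front is 85% monopolized
by the RFP-tagged strain, then quantify it:

```sh
$ printf 'edge_monopolization: 0.85\n' > colony_spec.yaml
$ adhesiometry simulate biofilm --spec colony_spec.yaml --seed 11 --out colony
wrote colony pair (edge fraction 0.853) to colony
$ adhesiometry biofilm --rfp colony/rfp.tif --gfp colony/gfp.tif --out seg.json
edge RFP fraction 0.840, superior RFP, ratio 5.24 (category 3)
```

The generator's realized rim fraction was 0.853 (pixel quantization of
the requested 0.85); the pipeline recovers 0.840 from the noisy images.
The ratio 5.24 is the superior strain's edge fraction over the
inferior's (0.840/0.160), falling in dominance category 3 of 5.

The same round trip for a force curve — a simulated 13.4 nN adhesion
event is recovered exactly in the noise-free case:

```sh
$ adhesiometry simulate curve --seed 3 --out curve
wrote curve (true F_max 13.4 nN) to curve
$ adhesiometry scfs --curves curve/curve.csv --out fmax.csv
extracted F_max from 1 curve(s) -> fmax.csv
$ cat fmax.csv
file,group,contact_time_s,fmax_nN,min_separation_um,baseline_slope_nN_per_um
curve.csv,,20.0,13.4,0.8020050125313283,0.0
```

And for aggregates (`qcam.csv` gains one row per image × size class plus
summary rows with across-replicate mean and SD):

```sh
$ adhesiometry simulate aggregate --seed 2 --out agg
wrote scene with 15 objects to agg
$ adhesiometry qcam --scenes agg/scene.tif --background agg/background.tif \
    --pixel-size-mm 0.02 --threshold 0.15 --out qcam.csv
```

The summary rows report class III covering 0.2012 mm²/cm² (10 objects)
and class IV covering 0.7512 mm²/cm² (5 objects), matching the simulated
object lists of 10 × 0.02 mm² and 5 × 0.15 mm².

Everything the CLI does is also available as a library
(`adhesiometry.qcam`, `.biofilm`, `.scfs`, `.stats`, `.synthetic`,
`.imaging`).

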