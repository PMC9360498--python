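# redoxim

Subcellular **optical redox imaging (ORI)** analysis for widefield
fluorescence microscopy of live cells: from paired NADH / Fp (oxidized
flavoprotein) channel images and per-cell ROIs to compartmental redox
indices, nuclear-to-cytoplasmic (N:C) area ratios, hierarchical group
summaries and an unequal-variance statistics battery — plus a synthetic
microscopy generator with exact ground truth, so every stage is testable
without any raw image download.

## The scientific problem

NADH and oxidized flavoproteins are endogenous fluorophores whose signals
report the cellular redox / metabolic state without labels.  The **optical
redox ratio**

    ORR = Fp / (Fp + NADH)

(higher = more oxidized) has been studied as a marker of cancer-cell
aggressiveness, e.g. to separate triple-negative breast cancer (TNBC) lines
from receptor-positive lines.  Most analyses average the whole cell; this
package implements the *subcellular* version: nucleus and cytoplasm are
quantified separately, and the redox indices are compared against the
classical morphometric marker, the N:C area ratio, under two replication
models (each culture dish as a replicate vs. each cell as a replicate).

The per-cell measurement chain:

1. **Background subtraction and SNR thresholding.**  Per channel, a pixel is
   kept iff `(raw − background) / noise_sd ≥ 7.5`, and it must pass in
   *both* channels to count anywhere (means, ratios, areas).
2. **Pixel-wise ratio image.**  `ORR = Fp / (Fp + NADH)` on retained pixels;
   compartment means are means of pixel ratios, not ratios of means.
3. **Compartment decomposition.**  Cytoplasm = whole-cell ROI minus nucleus
   ROI, exactly; pixel counts are conserved.
4. **Areas and N:C ratio.**  Areas are measured on the thresholded signal
   footprint with a 2×2 pattern-weight estimator (each window weighted 0,
   1/4, 1/2, 3/4, 7/8 or 1 by its on-pixel pattern); N:C = nuclear area /
   (whole-cell − nuclear area).
5. **Aggregation.**  Dish-based: cell → FOV → dish means, equal weights at
   each stage; cell-based: every cell is a replicate.  Pooling by cell line,
   receptor group or mitotic status.
6. **Statistics.**  Welch's t (raw samples or summary statistics, with
   Cohen's d), Brown–Forsythe one-way ANOVA (the unequal-variance F* on
   means), Dunnett's T3 pairwise comparisons via the studentized maximum
   modulus distribution, OLS regressions of nuclear on cytoplasmic indices,
   and a Welch-type test for the difference of two regression slopes.
   A significant change is only called **reliable** when it also exceeds a
   15 % magnitude threshold, guarding against residual instrument drift.

## Worked example

Generate the default synthetic study (four cell lines — two TNBC-like, two
receptor-positive-like — three dishes per line, three FOVs per dish, five
cells per FOV at realistic camera noise), analyze it, and compare nuclear
versus cytoplasmic redox state per receptor group:

```python
import numpy as np
import redoxim as rx
from redoxim.pipeline import RunConfig, analyze_records
from redoxim.aggregation import AnalysisMode, aggregate

bundle = rx.generate_study(seed=1)
records = analyze_records(bundle.fields, bundle.annotations, RunConfig())
summaries = aggregate(records, AnalysisMode("dish_based", "receptor_group"))

def get(group, index, comp):
    return next(s for s in summaries
                if s.group == group and s.index == index and s.compartment == comp)

for group in ("triple_negative", "receptor_positive"):
    nuc, cyt = get(group, "mean_orr", "nucleus"), get(group, "mean_orr", "cytoplasm")
    t = rx.welch_t(np.asarray(nuc.values), np.asarray(cyt.values))
    print(f"{group}: nuclear ORR {nuc.mean:.3f} +/- {nuc.sd:.3f}, "
          f"cytoplasmic {cyt.mean:.3f} +/- {cyt.sd:.3f} (N={nuc.n_replicates}), "
          f"{rx.percent_difference(nuc, cyt):+.1f}% (Welch p = {t.p_value:.2g})")
```

prints

```
triple_negative: nuclear ORR 0.660 +/- 0.011, cytoplasmic 0.563 +/- 0.014 (N=6), +17.3% (Welch p = 1.3e-07)
receptor_positive: nuclear ORR 0.400 +/- 0.019, cytoplasmic 0.400 +/- 0.019 (N=6), +0.0% (Welch p = 0.99)
```

— the TNBC-like group's nucleus is measurably more oxidized than its
cytoplasm, the receptor-positive-like group's is not, which is exactly the
contrast the generator encodes.  The same records give the cell-based N:C
comparison (`0.16 ± 0.04` vs `0.29 ± 0.14`, n = 90 per group, p ≪ 0.0001):
the TNBC-like group has the smaller relative nuclear footprint, but with a
smaller effect size than the redox indices.

The same workflow is available from the shell:

```sh
redoxim generate --preset study --seed 1 --out bundle/
redoxim analyze --in bundle/ --out results/
redoxim stats --records results/per_cell_records.csv --out results/
```

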