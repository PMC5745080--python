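# embryoquant

Quantification pipelines for whole-mount embryo micrographs, built for
studies of dorsoventral (D-V) patterning where two kinds of images must
be turned into numbers:

1. **Axis profiling** of a two-channel immunofluorescence image — a
   signaling readout (e.g. phospho-Smad1/5/8, the intracellular readout
   of active BMP signaling, in a Cy5 channel) against a DAPI nuclear
   counterstain. A rectangular ROI over the embryo is collapsed to a
   per-position profile along the ventral(0) → dorsal(1) axis, embryos
   are aligned onto a common normalized axis, and the per-position
   Cy5/DAPI ratio is averaged across embryos with SEM error bars.
2. **Angular extent** of a chromogenic in situ expression domain (e.g.
   the ventral mesoderm marker *eve1*, stained purple with NBT/BCIP).
   Pixels are classified as stain by an explicit RGB threshold rule,
   the binary mask is summed along rays at 360 angles within an ellipse
   traced around the embryo ("radial sums"), and the fraction of the
   circumference occupied by stain — occupied degrees / 360 — is the
   domain-size statistic.

Group differences (e.g. wild type vs a maternal-zygotic mutant with
expanded ventral BMP signaling) are tested with the two-sided
homoscedastic Student t-test; dispersion is reported as the standard
error of the mean, SEM = s.d./√n.

Because such studies typically deposit derived tables rather than raw
micrographs, the package ships a first-class synthetic phantom module:
two-channel gradient embryos with a known true signal/nuclear ratio
profile, and oval in situ embryos with a purple-stained rim sector of
known angular extent. Every stage of both pipelines is validated
against these ground truths and against independent brute-force
oracles. See `docs/methods.md` for the models, conventions and
numerical choices.

## Worked example

Simulate a wild-type-like group (true extents ~N(0.35, 0.05), n = 14)
and an expanded-domain group (~N(0.55, 0.05), n = 12) at 8-bit noise
s.d. 10, measure every embryo, and compare the groups:

```python
import numpy as np
from embryoquant import angular, workflows

rng = np.random.default_rng(0)
ellipse = workflows.default_embryo_ellipse(420, 520)
rule = angular.default_purple_rule()

frames, groups = [], []
for name, center, n in (("WT", 0.35, 14), ("mutant", 0.55, 12)):
    batch = workflows.simulate_insitu_batch(
        rng.normal(center, 0.05, n), noise_sigma=10.0,
        seed=int(rng.integers(2**31)),
    )
    frames += [img for img, _ in batch]
    groups += [name] * n

table = workflows.extent_table(frames, [ellipse] * len(frames), groups,
                               rule=rule, signal_min=2)
print(table.groupby("group")["extent_fraction"].agg(["mean", "count"]))
result = workflows.compare_groups(table, "extent_fraction")
print(result[["mean_a", "sem_a", "mean_b", "sem_b",
              "t_stat", "df", "p_value"]].to_string(index=False))
```

Output:

```
            mean  count
group
WT      0.341865     14
mutant  0.554398     12
  mean_a    sem_a   mean_b    sem_b     t_stat   df      p_value
0.341865 0.012359 0.554398 0.010602 -12.817498 24.0 3.156219e-12
```

The measured extent fractions recover the simulated group centers (the
mutant domain occupies ~55% of the circumference vs ~34% in WT), and
the pooled-variance t-test on 24 degrees of freedom rejects the null
decisively — the pattern expected when ventral BMP signaling expands.

## Command line

The same stages are exposed as subcommands of `embryoquant`:

```sh
embryoquant simulate-insitu --sector 250,330 --noise-sigma 10 --out embryo.png
embryoquant extent embryo.png --ellipse 120,150,130,100 --signal-min 2 --out-dir out/
embryoquant simulate-gradient --ratio "1 + 2*x" --noise-sigma 5 --out embryo.tif
embryoquant profile embryo.tif --roi 50,25,200,650 --out-dir out/ --plot
embryoquant compare out/extent.csv --value-col extent_fraction --out-dir out/
embryoquant run config.yaml          # full workflow from a YAML config
```

Every output CSV starts with a comment line recording the seed and a
hash of the run configuration, so any table can be traced back to the
exact run that produced it, and identical configs reproduce outputs
byte for byte.

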