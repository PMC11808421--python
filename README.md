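# colocpcc

Pearson-correlation colocalisation analysis for two-channel fluorescence
microscopy, with the pixel-selection criterion made explicit.

## The problem

Colocalisation analysis asks to what degree two fluorescent labels occupy
the same diffraction-limited volume. The standard metric is the Pearson
correlation coefficient (PCC) of the paired pixel intensities
$(R_i, G_i)$:

$$
\mathrm{PCC} \;=\;
\frac{\sum_{i \in S}(R_i-\bar R)(G_i-\bar G)}
     {\sqrt{\sum_{i \in S}(R_i-\bar R)^2}\,\sqrt{\sum_{i \in S}(G_i-\bar G)^2}},
$$

where $-1$ indicates mutual exclusion, $0$ no relation and $+1$ perfect
colocalisation. What is rarely stated is the pixel set $S$ over which the
sums (and the means $\bar R,\bar G$) run. Three conventions circulate in
analysis software, and they can return wildly different numbers **for the
same image**:

- **ALL** — every pixel, thresholds ignored. Sensitive to the
  foreground-to-background ratio: object size, density and even canvas
  size move the value.
- **OR** — pixels strictly above the intensity threshold in at least one
  channel. Reflects both signal co-occurrence and intensity
  proportionality.
- **AND** — pixels strictly above the thresholds in both channels.
  Insensitive to co-occurrence by construction; excels at detecting small
  amounts of true colocalisation.

`colocpcc` is aimed at microscopists and image analysts who want to
compute all three coefficients side by side, understand why they diverge,
and report defensible statistics: Otsu or Costes thresholding,
cytofluorogram quadrant summaries, z-range analysis for stacks, rotation
and scramble randomisation nulls, Student's t-tests and Hedges' g.

## Worked example

Two partially overlapping uniform squares (intensity 0.8, 25% area
overlap) on a 1000 × 1000 zero background, swept over square side with
fixed thresholds of 0.1:

```python
from colocpcc import object_size_sweep
print(object_size_sweep([2, 80, 160, 320, 660]).round(4).to_string(index=False))
```

```
 side  area_ratio  pcc_all  pcc_or  pcc_and  and_degenerate
    2      0.0000   0.2500   -0.75      1.0            True
   80      0.0128   0.2452   -0.75      1.0            True
  160      0.0512   0.2303   -0.75      1.0            True
  320      0.2048   0.1644   -0.75      1.0            True
  660      0.8712  -0.3288   -0.75      1.0            True
```

Spatial overlap and intensity proportionality are identical in every row
— only the object size changes — yet the all-pixels coefficient drifts
from +0.25 to −0.33. The thresholded coefficients are size-invariant:
OR is exactly −0.75 (most selected pixels carry signal in only one
channel) and AND reports 1.0 under the zero-variance convention (both
channels are constant at 0.8 inside the overlap; the `and_degenerate`
flag marks the 0/0 convention).

A sparser mock: five identical Gaussian spots per channel, exactly one
spot pair coincident, thresholds from Otsu's method:

```python
from colocpcc import (SpotPairSpec, Criterion, make_spot_pair,
                      otsu_threshold_pair, compute_pcc)
pair = make_spot_pair(SpotPairSpec())
thr = otsu_threshold_pair(pair)
for c in Criterion:
    r = compute_pcc(pair, thr, c)
    print(f"{c.value:>4}: PCC = {r.value: .2f}  fraction selected = {r.fraction_selected:.4f}")
```

```
 all: PCC =  0.19  fraction selected = 1.0000
  or: PCC = -0.58  fraction selected = 0.0158
 and: PCC =  1.00  fraction selected = 0.0018
```

One image, three verdicts: "no relation" (ALL), "mutual exclusion" (OR),
"perfect colocalisation" (AND). Each is correct about the property it
actually measures, which is why the criterion must be reported alongside
the coefficient.

The same operations are available from the shell:

```bash
colocpcc synth --kind squares --side 80 --out-green g.tif --out-red r.tif
colocpcc pcc --green g.tif --red r.tif --threshold-mode fixed \
         --threshold-green 0.1 --threshold-red 0.1 --out pcc.csv
colocpcc sweep --sides 2,80,160,320,660 --out sweep.csv
```

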