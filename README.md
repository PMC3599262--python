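# uptakeflow

Tools for quantifying nanoparticle (NP) uptake by cells from imaging-flow-
cytometry-style single-cell images. The central question the package answers
is: of the probe signal associated with a cell, how much is truly
**internalized** and how much is merely **adsorbed on the cell surface**?

It is aimed at cell biologists and nanotoxicologists who export per-event
images (brightfield + fluorescence, optionally side scatter) from an imaging
flow cytometer as TIFF, and at anyone who needs the companion arithmetic for
classic flow-cytometry quench and inhibition experiments.

## The method

For each event a **whole-cell mask** M is segmented from the brightfield
image (Otsu threshold on the deviation from the background, hole filling,
largest connected component). An **internal mask** M_int is obtained by
eroding M inward by a fixed physical depth d — by default d = 3 µm, i.e.
6 px at the instrument's 0.5 µm/px — implemented as a Euclidean
distance-transform threshold:

    M_int = { p ∈ M : dist(p, ∁M) ≥ d }

The ring M \ M_int is the membrane shell where surface-adsorbed particles
sit. Summing a channel over the two compartments gives I_in and I_out
(I_total = I_in + I_out), and the per-cell **Internalization Score**

    IS = log10( (I_in + ε) / (I_out + ε) ),   ε = 1 intensity unit

is positive when signal is mostly internalized, negative when mostly
surface-bound, and exactly zero for an equal split. The same machinery
applies to a side-scatter channel, a label-free proxy for light-diffracting
particles such as TiO₂.

Around the per-cell score the package provides:

- **Population summaries** — MFI (median for classic flow cytometry, mean
  for the imaging path) and mean IS ± SD per condition, with debris/QC
  exclusion.
- **Trypan-Blue quench arithmetic** — TB extinguishes extracellular
  fluorescence, so internalized% = 100 · MFI_withTB / MFI_withoutTB (an
  optional quench-efficiency parameter models incomplete quenching).
- **Inhibition percentages** — 100 · (1 − (MFI_cond − bg)/(MFI_ref − bg)).
- **Pearson colocalization** — plain pixel-wise Pearson r within a mask,
  aggregated as mean ± SD over images.
- **One-way ANOVA + Bonferroni post hoc** group comparisons.
- A **synthetic event generator** that renders single cells with a known
  split of probe intensity between interior and membrane shell, so the whole
  pipeline is testable against exact ground truth without instrument data.

## Worked example

Simulate a 100-cell cohort (default conditions: 8 µm cells, 3 µm membrane
shell, 75% of a 10,000-unit probe budget internal) and run the full
pipeline:

```sh
uptakeflow simulate --n 100 --seed 17 --out demo/events
uptakeflow run --in demo/events --out demo/out
head -3 demo/out/summary.csv
```

```
# config_hash=b9b5e7a2e3d33782
condition,n_cells,MFI,mean_IS,sd_IS,statistic_used,low_n_warning
events,100,11624.706990382725,0.37560078757062515,0.000654374523378804,mean,True
```

A perfectly segmented, background-free 75%-internal cell would score
IS = log10((7500+1)/(2500+1)) ≈ 0.477; the cohort mean of 0.376 is lower
because the uniform background (2 units/px) contributes relatively more to
the larger shell area than to the interior. The positive sign says the
cohort is internalization-dominated, exactly as generated (run with
`--background median_outside` on the `features` subcommand to remove the
offset). `low_n_warning` reminds you that fewer than 500 cells were
analyzed. Quench arithmetic on a flow-cytometry table:

```sh
uptakeflow quench --in fcm.csv
```

```
4h: internalized 75.0% (adsorbed 25.0%)
24h: internalized 90.0% (adsorbed 10.0%)
```

i.e. an MFI that drops 25% after Trypan Blue means 75% of the probe was
internalized. Other subcommands: `segment`, `features`, `coloc`, `stats`
(`uptakeflow --help`).

As a library:

```python
from uptakeflow import CellSpec, make_cell_event, intensity_partition, internalization_score
from uptakeflow.segmask import compute_masks

event = make_cell_event(CellSpec(internal_fraction=0.7), seed=1)
masks = compute_masks(event.brightfield)
i_in, i_out, i_total = intensity_partition(event, masks)
print(internalization_score(i_in, i_out))
```

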