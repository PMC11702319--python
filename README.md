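# fjordapcs

Source apportionment for fjord water-column geochemistry.

Glacierized Arctic fjords receive freshwater from marine-terminating
(subglacial discharge) and land-terminating (proglacial river) glaciers, and
the imprint of that freshwater on carbon, nutrient and trace-element
distributions is entangled with pelagic cycling and benthic fluxes.
`fjordapcs` implements the chemometric pipeline used to disentangle and
*quantify* those processes from a modest station × depth survey table
(salinity, temperature, NO₃⁻, NO₂⁻, Si(OH)₄, PO₄³⁻, A_T, C_T, and dissolved
trace elements), built around the Kongsfjorden (West Svalbard) study system.

## The method

Starting from the standardized concentration matrix **Z** (n samples × p
parameters, below-LOD values imputed uniformly on [0, LOD)):

1. **PCA with varimax rotation.** Eigen-decomposition of the correlation
   matrix in the convention **Z** = **P B**ᵀ (loadings **B** are
   variable–component correlations, scores **P** have unit variance).
   Components are retained by the Guttman–Kaiser criterion (λ > 1, with a
   fixed-k override for scree judgement) and rotated to simple structure.
2. **Broken-stick loading significance.** A loading is significant when its
   squared value exceeds the broken-stick expectation
   b_m = (1/k) Σ_{i=m..k} 1/i at its rank.
3. **Independence check.** Scores are discretized into four equal-width
   bins and component pairs are chi-square tested for independence.
4. **Ward clustering** of parameters in loading space (squared-Euclidean
   criterion) groups constituents by shared process affinity.
5. **APCS-MLR.** Scores are re-zeroed against an artificial
   zero-concentration sample (absolute principal component scores); each
   parameter is regressed on the APCS with backward elimination at
   P ≥ 0.1, and the mean absolute modeled contributions are normalized into
   percentage shares R_S per process.
6. **Endmember mixing.** For parameters significant on the conservative
   mixing component, partial values P·B (de-standardized) are regressed on
   salinity to extrapolate a freshwater endmember (S = 0) and a marine
   endmember (S = 34.86); river endmembers are means ± population SD of the
   proglacial outlet samples, and estuarine removal factors compare river
   sources against receiving surface water.
7. **Hydrography.** Cottier-style T–S water-mass classification and
   freshwater content, FWC = ∫ (S_ref − S(z))/S_ref dz with S_ref = 34.86.

A synthetic fjord generator with three latent processes (mixing, pelagic,
benthic), known loadings, contribution shares and endmembers makes every
stage verifiable against ground truth without the original survey data.

## Worked example

```sh
fjordapcs simulate --outdir sim --seed 11     # synthetic survey table
fjordapcs run --input sim/table.csv --schema sim/schema.yaml --outdir out
```

```
wrote 103 samples x 18 parameters to sim
k = 3, eigenvalues = [9.77 5.78 2.31 0.02 0.02], outputs in out
```

Three components pass the Guttman–Kaiser screen (eigenvalues 9.77, 5.78,
2.31 of 18; rotated variance fractions 51.5 / 31.3 / 16.4 %). The
apportionment table (`out/apportionment.csv`) gives, per parameter, the
rotated loading, the contribution share R_S and its significance code per
process — e.g. for total alkalinity the mixing component carries 90 % of the
distributional change:

```
     PC1 loading  PC1 R_S (%) PC1 P  PC2 loading  PC2 R_S (%) PC2 P  PC3 loading  PC3 R_S (%) PC3 P
AT          0.98        90.20   ***         0.13         4.76   ***         0.08         5.04   ***
CT          0.87        76.55   ***         0.47        16.87   ***         0.11         6.58   ***
NO2         0.17        26.18   ***         0.97        60.61   ***         0.13        13.21   ***
NO3         0.15        24.99   ***         0.98        64.49   ***         0.10        10.52   ***
```

and `out/endmembers.csv` holds the mixing-line extrapolations — here the
synthetic dAl freshwater endmember is ≈ 64,500 ng L⁻¹ against a marine value
of ≈ 5,800 ng L⁻¹, while the A_T extrapolation is negative and flagged (the
statistical artifact that strong non-conservative behavior produces):

```
  parameter   slope  intercept  endmember_s0  endmember_s34.86  r_squared  negative_flag
0        AT    89.7     -844.8        -844.8            2281.1        1.0           True
2       dAl -1683.4    64465.6       64465.6            5782.9        1.0          False
```

`out/freshwater_content.csv` adds per-station FWC (m), FWC_sp (%) and the
modal water mass.

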