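# tatascan

Regulatory SNP scoring in TATA-binding-protein (TBP) binding sites of
proximal promoters.

Most promoter variants are silent; the interesting ones change how
strongly the basal transcription machinery engages the core promoter.
`tatascan` is a small analysis toolkit for the in-silico arm of that
question: given a 70-bp proximal promoter (the region upstream of the
TSS where functional TBP sites concentrate) and a substitution SNP, it
estimates the TBP–DNA equilibrium dissociation constant K_D for each
allele, decides whether the minor allele significantly shifts it, and
aggregates such calls into selection-pressure statistics. It is aimed
at researchers triaging unannotated promoter SNPs into candidate
markers of expression change before any wet-lab or cohort work.

## The model

TBP–DNA affinity is handled throughout on the `−ln(K_D in M)` scale
(larger = tighter binding; 39 nM ↔ 17.06 ln units). A 26-bp window is
scored as a linear combination of three sequence terms mirroring the
elementary steps of TBP–TATA recognition — TBP slides along the minor
groove, stops at the recognition element, and bends the site:

    −ln K_D = b₀ + b_slide·f_TA + b_stop·S_PWM + b_bend·ΔG_site

* `f_TA` — TpA dinucleotide-step density of the window (sliding and
  minor-groove deformability),
* `S_PWM` — best log-odds match of any 15-bp sub-window to the
  canonical TATA-box position count matrix (the stop signal),
* `ΔG_site` — mean nearest-neighbour stacking free energy of that
  15-bp site (weakly stacked DNA bends more cheaply).

A promoter is scored by its single best (minimal-K_D) 26-bp window, so
a 26-bp probe reproduces its own window score exactly. The
coefficients ship pre-calibrated by least squares against a ten-probe
reference panel (five SNPs × two alleles with published predicted
affinities); `TbpAffinityModel.fit` re-runs that calibration on any
panel.

Downstream of the affinity estimate:

* **Allele comparison** — Δln K_D = (−ln K_D)ₘᵢₙ − (−ln K_D)wt, a
  Z statistic `Z = Δ/σ√2` with the model uncertainty σ (default
  0.20 ln units), a one-sided normal tail α, a directed decision
  (“deficiency”/“excess”, significant at α < 0.05), a heuristic A–E
  priority rank, and an expression ratio exp(Δ).
* **Selection statistics** — exact binomial tails over marker counts:
  against the genome-wide norm that TBP-site damage is fourfold more
  frequent than improvement (null p₀ = 0.2 for affinity-increasing
  markers), and a two-sided equal-split test whose non-rejection is
  the operational signature of disruptive selection.
* **Validation layer** — prediction-vs-experiment tables with Pearson,
  Spearman, Kendall τ-b and Goodman–Kruskal γ, and saturation-kinetics
  fitting `v = Vmax·c/(K_D + c)` for EMSA rate-vs-concentration data.
* **Synthetic data** — seeded generators for promoters with planted
  TATA elements and SNPs of known effect direction, marker-count
  tables under chosen improve:damage regimes, and noisy kinetics
  curves.

## Worked example

Score the packaged verification panel (five promoter SNPs; any
promoter FASTA + SNP TSV works the same way):

```bash
python -c "from tatascan import fixtures, io; \
  io.write_promoters(fixtures.panel_promoters(), 'promoters.fasta'); \
  io.write_snps(fixtures.panel_snps(), 'snps.tsv')"
tatascan scan promoters.fasta snps.tsv -o calls.tsv
```

`calls.tsv` then contains:

```
rsid          gene    delta_ln_kd  decision                 rho
rs1452787381  SHOX    -0.910       deficiency: significant  C
rs1393008234  GTPBP6  +0.852       excess: significant      D
rs1402972626  ASMT    +0.416       insignificant
rs1452787381  ZFY     +0.777       excess: significant      D
rs20067072    CDY2A   -0.914       deficiency: significant  C
```

A negative Δln K_D (SHOX, CDY2A) means the minor allele weakens TBP
binding — predicted underexpression (“deficiency”); positive Δ means
tighter binding and predicted overexpression.

Compare predictions with EMSA measurements and compute the panel
correlations:

```bash
tatascan validate --fixture panel
```

```
scale     pearson_r  pearson_p  spearman_rho  ...  gk_gamma  n
absolute  0.8392     0.0024     0.811              0.7209    10
relative  0.9829     0.0027     1.0                1.0       5
```

`absolute` correlates per-allele −ln K_D (10 probes), `relative` the
per-SNP Δln K_D (5 pairs): the predicted direction and ordering of
allele effects track the measurements closely even though the absolute
K_D scales of model and assay differ.

Selection-pressure statistics on the packaged marker-count table:

```bash
tatascan selection --fixture counts
```

prints, for the TOTAL row (261 markers, 176 affinity-increasing vs 85
decreasing; 119 potential-increasing vs 142 decreasing),
`p_norm_null ≈ 1.1e-61` (the 2:1 excess of affinity-increasing markers
is wildly incompatible with the 1:4 genome norm — selection against
underexpression) and `p_equal_null ≈ 0.17` (the up/down split is
statistically even — the disruptive-selection signature).

## Layout

| module | contents |
|---|---|
| `tatascan.records` / `tatascan.io` | domain types, FASTA/TSV/VCF readers and writers |
| `tatascan.affinity` | the slide/stop/bend scorer, `TbpAffinityModel` estimator, unit conversions |
| `tatascan.zscore` | allele comparison: Δ, Z, α, decision, rank |
| `tatascan.selection` | exact binomial selection-pressure statistics |
| `tatascan.validation` | comparison tables, four correlation measures, plots |
| `tatascan.kinetics` | `SaturationKinetics` one-site binding fit |
| `tatascan.simulate` | seeded synthetic-data generators |
| `tatascan.fixtures` | packaged verification-panel and count-table fixtures |
| `tatascan.cli` | `tatascan scan/selection/validate/kinetics-fit/simulate` |

See `docs/methods.md` for the modelling assumptions, parameter
defaults and known limitations.
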