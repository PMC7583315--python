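# Methods

## Scope and data flow

`tatascan` reimplements, as a tested pipeline, the desk-scale analysis
of regulatory SNPs in TBP-binding sites of 70-bp proximal promoters:
per-allele affinity estimation → per-SNP significance call →
marker-count selection statistics, with a validation layer (unit
bookkeeping, correlation panel, saturation-kinetics fitting) and
synthetic-data generators in place of any genome/dbSNP retrieval.
Users supply promoter sequences and SNP tables; there is no network
access anywhere in the package.

Coordinates: promoters are the 70 bp upstream of the TSS on the sense
strand; SNP offsets are 1-based negative distances (−45 = 45th base
before the TSS), internally index 0 ↔ offset −70. Substitutions only;
indels are rejected with a clear error. Reverse-strand TATA elements
are not scanned (documented limitation below).

## The affinity model

TBP–promoter binding is summarised by one number per allele,
−ln(K_D in molar). A 26-bp window is scored as

    −ln K_D = b0 + b_slide · f_TA + b_stop · S_PWM + b_bend · dG_site

with three sequence terms chosen to mirror the elementary recognition
steps (sliding, stopping, bending):

* `f_TA`: TpA step density over the window's 25 dinucleotide steps.
  TpA is the weakest stacked, most deformable step; its density is a
  proxy for one-dimensional sliding and minor-groove pliability.
* `S_PWM`: the best log-odds score of any 15-bp sub-window against the
  canonical TATA-box position count matrix (389 aligned sites,
  consensus cTATAWAWR plus a G-rich downstream stretch), Laplace
  pseudocount 1.0, uniform background.
* `dG_site`: mean unified nearest-neighbour stacking free energy
  (kcal/mol, 37 °C) over that best 15-bp sub-window; less negative =
  cheaper to bend.

A promoter of length ≥ 26 is scored by the single best (minimal K_D)
window — the aggregation is a maximum, not a Boltzmann sum — so a
26-bp probe reproduces its own window score exactly and the scan is
equivalent to explicit window enumeration (property-tested).

### Calibration

The original scoring service's coefficient tables are not published in
a recoverable form, so the linear combination is calibrated by
ordinary least squares against the ten published predicted −ln K_D
values of the verification panel (five SNPs × two 26-bp alleles); the
fitted configuration ships as `data/tbp_model.yaml` and
`fixtures.calibrate_model()` reproduces it from the packaged panel.
All three fitted coefficients come out positive, i.e. physically
interpretable (TA density, PWM match and site deformability all favour
binding).

Calibration diagnostics are computed, not assumed: the fit reaches
Pearson r ≈ 0.97 against the printed ten-value column and recovers all
five printed allele-difference signs, but its residuals are of order
0.2 ln units and the leave-one-out residuals reach ≈ 0.65 ln units.
Four free parameters on ten highly structured values cannot
interpolate them; the surrogate reproduces ordering, directions and
magnitudes at the few-tenths level, not the printed third decimal.
Model variants examined during design (pseudocount, window-level vs
site-level stacking term, both-strand scanning, soft-max aggregation,
alternative composition features) all plateau at the same level, which
is why the shipped default is the simplest interpretable variant
rather than a more elaborate one.

### Uncertainty

Each estimate carries a single standard error σ, the model's
regression residual SD, a configuration constant (default 0.20 ln
units) rather than a per-sequence quantity. The default is chosen so
that the five in-vitro-verified allele differences (smallest printed
|Δ| = 0.51) are significant at α < 0.05 under the Z-test below; it is
overridable (`--sigma`, or `residual_sd_sigma` in the config).

## Allele comparison

For estimates that share a configuration,

    Δ = (−ln K_D)_min − (−ln K_D)_wt,   Z = Δ / sqrt(σ² + σ²),

α is the one-sided standard-normal tail beyond |Z| (the direction is
taken from the sign of Δ, so one α per directed decision);
"deficiency: significant" iff Δ < 0 and α < 0.05, "excess" for Δ > 0.
The expression change is reported as the ratio exp(Δ) under the
working premise that expression scales proportionally with
TBP–promoter affinity; no attempt is made to model absolute mRNA
levels. The A–E priority rank bins
(α ≤ 1e-6, 1e-4, 1e-3, 1e-2, < 0.05) are a heuristic, exposed in
configuration; a tail that underflows to exactly 0 maps to rank A. No
multiple-testing correction is applied across SNPs — calls are
per-SNP screening scores, not family-wise inferences.

A consequence of the composite scorer worth stating: an edit moving a
near-degenerate PWM position toward consensus raises the stop term but
can in principle be offset by the composition terms. Monotonicity
toward consensus is therefore guaranteed (and tested) for the stop
term and for max-over-windows aggregation; the synthetic generator
verifies every improve/damage SNP against the full scorer instead of
assuming it.

## Selection statistics

Significant calls are tallied per gene class into rows
(N_RES = N_> + N_<; N_up/N_dn through literature-curated annotations,
consumed as data). Two exact binomial hypotheses per row, always by
pmf summation (via the regularised incomplete beta), never a normal
approximation, because rows can have N_RES ≈ 12:

* genome norm: affinity-increasing markers ~ Binomial(N_RES, p0 = 0.2)
  (the fourfold excess of TBP-site damage over improvement
  genome-wide). Rows above the norm report the right tail
  P(X ≥ N_>); rows at/below it report the cumulative P(X ≤ N_>), and
  the reported tail is labelled so the two conventions are never
  silently mixed — the source tables mix them, printing cumulative
  values for norm-consistent reference rows.
* equal split: N_up ~ Binomial(N_up + N_dn, 1/2), two-sided by the
  minimum-likelihood rule. The packaged 119/142 split gives p ≈ 0.17
  (one-sided 0.087), comfortably above the printed > 0.06 bound under
  either convention.

The packaged count table stores the printed digits verbatim, including
their internal inconsistencies (per-class N_> sums to 177 against a
printed total of 176, and one row's digits disagree with the
accompanying text); the fixture notes flag these rather than
resolving them.

## Validation layer

The comparison table recomputes measured −ln K_D from nM values
(−ln(K_D·10⁻⁹)) and forms Δ within WT/minor pairs. Association
measures: Pearson r with the t-transform p (n − 2 d.f.), Spearman ρ,
Kendall τ-b (tie-corrected), Goodman–Kruskal γ = (C − D)/(C + D) with
tied pairs excluded; the τ variant and the tie handling for γ are
fixed choices, documented here because the convention is not standard
across software. The known absolute-scale offset between model and
assay (different active-TBP concentrations, a non-binding dimer
fraction in the assay) is deliberately not modelled; only ordering and
differences are compared. The regression line and 95 % band in the
plot are figure artefacts, not inference.

## Kinetics fitting

`v = Vmax·c/(K_D + c)` by bounded nonlinear least squares;
initialisation Vmax₀ = max rate, K_D₀ = concentration nearest
half-max; SEMs from the covariance at the optimum;
`identifiability_warning` when max(c) < fitted K_D (no saturation
observed). Raw gel quantitation is out of scope — the module starts
from (concentration, rate) tables, as the cited assay software does.
On noiseless data the fit recovers generating parameters to 1e-6
relative; the Monte-Carlo recovery study (500 seeded four-point
datasets at 5 % Gaussian noise, concentrations 0.25–4×K_D) keeps the
median K_D bias within ±10 %.

## Synthetic data

The generators emulate the study conditions, with ground truth:

* Promoters: 70-mers over an adjustable GC background (default 0.5)
  with the scorer's own 15-bp PWM consensus planted at a configurable
  offset (default 20, i.e. offsets −50…−36) — using the model's PWM
  for planting makes "improve/damage" well-defined relative to the
  scorer. Damage SNPs replace the consensus base at the
  most-informative core position with the lowest-count base; improve
  SNPs do the reverse on a correspondingly weakened core (improving a
  perfect-consensus core is refused); neutral SNPs fall outside every
  window containing the core and are verified to leave the promoter
  score exactly unchanged. All SNPs are verified against the scorer
  with rejection over fresh backgrounds.
* Count tables: N_> ~ Binomial(N_RES, improve_fraction),
  N_up ~ Binomial(N_RES, up_fraction); defaults (261, 0.2, 0.5).
* Kinetics: default truth K_D = 100 nM, Vmax = 1, noise SD 0.05,
  four concentrations (25, 50, 100, 400 nM) — four-point curves
  matching the assay design.

One seeded `numpy` Generator per call; identical seeds give
byte-identical outputs. What the generators do **not** emulate: real
base composition of the Y chromosome, gene structure, recombination
(PAR) boundaries, allele-frequency spectra, or TATA-less promoter
classes. Passing the synthetic recovery tests therefore demonstrates
internal consistency of scorer + caller, not accuracy on genomic
sequence.

## Problem sizes and numerical choices

Test-suite and acceptance-script problem sizes — 500 kinetics
datasets, 200 count-table seeds, 100 end-to-end promoters, brute-force
window enumeration up to L = 200, exhaustive binomial oracle to
n = 30 — are chosen as the smallest sizes at which the corresponding
statistical claims are stable across seeds. Ties in the best-window
argmax resolve to the leftmost window; sequence input is uppercased;
degenerate inputs (constant vectors, empty call lists, zero-count
rows) return defined values or raise typed errors as documented in the
module APIs.

## Known limitations

* Sense-strand scanning only; a TATA element on the reverse strand is
  invisible.
* The calibration surrogate's absolute accuracy is bounded by the
  ten-point panel (see Calibration); per-SNP α values should be read
  as screening scores.
* The annotation layer (expression direction → reproductive-potential
  effect) is consumed as curated data; the package performs no
  literature inference.
* The equal-split "disruptive selection" reading is an operational
  statistical statement about count symmetry, not a population-genetic
  selection inference (no dN/dS, no site-frequency spectra).
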