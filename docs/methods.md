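# Methods

## Model

The system is a discrete-generation, two-sex population segregating a
biallelic X-linked locus: an engineered sexually antagonistic allele
(SAA) versus a control allele. Five classes are tracked — SAA and
control hemizygote males; SAA-homozygote, heterozygote and
control-homozygote females. Assumptions:

- non-overlapping generations, fixed adult census (default 100 males +
  100 females), no density dependence, mutation or migration;
- 1:1 sex ratio at birth; no meiotic drive; no recombination between
  the allele and its eye-colour marker (they are tightly linked);
- every female mates exactly once per generation. Sperm competition is
  neutral between the two male genotypes, so with multiple mating the
  sired-offspring shares would equal the mating shares anyway —
  single mating loses no generality for the frequency recursion;
- the SAA male advantage acts only on mating success and only in the
  light; female costs act only on fecundity and are expressed mainly
  in homozygotes.

One generation maps the state `(m, f)` (per-sex genotype frequencies)
through: mating proportions `C[i,j] = s_i f_j` with male shares `s`
tilted by the cycle-averaged weight `w_eff`; offspring pool
`Σ_{ij} C[i,j] · F[i,j] · M(i,j)` where `F` is the cross fecundity
table and `M(i,j)` the Mendelian X-linked offspring distribution; and
per-sex renormalization. Generation indexing starts at 1 (the founding
adults).

The reported statistic is the SAA frequency among X chromosomes,
`q = (m_SAA·N_m + (2f_SS + f_het)·N_f) / (N_m + 2N_f)`, with sexes
weighted by their actual census sizes — necessary because the
low-frequency founding cages deliberately hold 90 males to 100
females, and 3% only emerges under X-chromosome counting (9/290).

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `w_photo` | SAA male mating weight in the light (control = 1) | **required** | an empirical input measured from paired trials or cage spot checks; it has no defensible default |
| `light_hours` | hours of light per 24 h | 12 | the standard 12:12 husbandry cycle |
| `light_dark_propensity` | fraction of matings in light vs dark at 12:12 | 0.402 : 0.598 | flies mate slightly more in the dark; the split is an empirical constant of the system |
| `female_fecundity` | relative fecundity of SS / het / control mothers | 0.388 / 0.9 / 1.0 | the rudimentary empirical estimates that also parameterize the founding-composition ladder |
| `brood_size` | surviving offspring per control-mother mating | 30 | gives an offspring pool of ~3000 per 100-female cage at low SAA frequency, inside the 2500–5400 range typical of the protocol |
| `sample_size` | offspring scored (and propagated) per generation | 300 | the cage protocol's 300-larva draw |
| `n_runs` | ensemble size | 100 | standard replicate count for the confidence band |
| `max_generations` | equilibrium horizon | 1000 | equilibria are converged well before this under all parameterizations examined |

`w_photo` (photophase-only, measurable) and `w_eff` (cycle-averaged,
used by the recursion) are deliberately distinct objects; configs
always specify `w_photo` and the package derives `w_eff`.

The photoperiod interpolation scales the 0.402:0.598 propensities
linearly with hours of light and dark and renormalizes:
`p_L = 0.402·(L/12) / (0.402·(L/12) + 0.598·((24−L)/12))`. It is the
simplest form consistent with the three anchors — `p_L(12) = 0.402`,
`p_L(0) = 0`, `p_L(24) = 1` — which is all the system's description
pins down.

### Reference calibration

The cage-observed photophase mating success and the full cross-specific
offspring table are not published numerically, so the quantitative
equilibrium is reproduced by calibration: with the default fecundities,
root-finding on the deterministic recursion gives `w_photo* = 1.9331`
(`w_eff = 1.3751` at 12:12) as the advantage whose 1000-generation
equilibrium is 0.126. The equilibrium is monotone in `w_photo`, so the
root is unique in the bracket. All qualitative results (invasion when
rare, decline when common, a single interior equilibrium reached from
either side, extinction in permanent dark) hold across the bracket and
do not depend on the exact calibrated value. A measured `w_photo` and a
measured cross-fecundity table can be supplied via config and replace
the calibration wholesale.

## Founding compositions

`hw_selection_composition` weights Hardy–Weinberg class frequencies by
fitness, renormalizes within sex, scales to 100 and rounds each class
to the nearest integer (half away from zero) with **no reconciliation**
— so a sex can total 99, a quirk the published ladder exhibits and the
procedure preserves. Two conventions follow from that quirk:

- quoted SAA percentages are computed against the *design* census
  (100 + 2·100 X chromosomes), not the realized 99-female totals;
  `composition_percent` takes the census override for this purpose;
- the published highest-frequency composition (94, 6, 64, 33, 2)
  corresponds to a pre-selection frequency of ≈0.8995, not 0.90
  exactly: at q = 0.90 the unrounded SAA-homozygote female class is
  64.63, which rounds to 65. The procedure reports 65 at q = 0.90; the
  published quintuple ships verbatim as the `P8` preset.

The 3% founding composition (9 SAA males, 81 control males, 100
control females) is a direct construction, not a ladder rung, and is
provided as presets `P1`–`P4`.

## Stochastic model and ensembles

The 300-offspring draw is a single multinomial over the five classes
at the deterministic pool proportions. The protocol actually samples
without replacement from a realized pool of 2500–5400; the
hypergeometric variance correction `(N−n)/(N−1)` is at most ~6% there,
so the multinomial is the default and an `exact_pool` mode (integerize
the pool at one brood per female, draw multivariate-hypergeometric) is
available for sensitivity checks. A draw that leaves a sex empty marks
the line failed (terminal status, not an exception); absorbed runs
(loss or fixation) stay at the absorbed frequency and remain in
ensemble averages, since no censoring rule is part of the design.
Ensemble bands are percentile (2.5/97.5) across runs; with weak
selection and 300-sample drift many 700-generation runs absorb at
loss, so the lower band edge can be 0 while the band still brackets
the deterministic equilibrium. Per-run generators are spawned from the
master seed via `SeedSequence`, making ensembles and synthetic
datasets bit-reproducible.

## Synthetic cage data

`generate_experiment` emulates the observable record of the protocol:
the multinomial draw of each stochastic step *is* the scored offspring
table (so analysis round-trips exactly); the adult census is rebuilt
from the drawn proportions with per-sex largest-remainder rounding
(summing exactly to the census — reconciliation is appropriate here
because the census is physically restocked, unlike the founding-ladder
arithmetic); spot-check matings are independent photophase Bernoulli
events with SAA win probability `w_photo·m₁/(w_photo·m₁ + m₂)`,
defaulting to 6 per generation (the original record is 62 observations
over 10 generations). The generator's recorded "truth" series is the
SAA X-frequency of the drawn offspring counts at their realized
per-sex totals — the same statistic the trajectory analysis computes.

What the generator does **not** emulate: viability differences beyond
the fecundity scalars, development-time or ejaculate-depletion
effects, overlapping generations, counting error beyond the optional
uniform within-sex misclassification rate. Passing round-trip and
recovery tests therefore shows the analysis chain is faithful to this
generative model, not that real cages lack those complications.

## Numerical choices

- Convergence: a deterministic run is flagged converged after |Δq| <
  1e-10 for 10 consecutive generations; equilibria are read at the
  final generation regardless.
- Calibration root-finding: Brent's method, xtol 1e-10, bracket
  (1.05, 30) by default.
- Rounding: founding ladder — nearest integer per class, half away
  from zero, unreconciled; adult census — nearest integer then
  largest-remainder adjustment to the census.
- Degenerate inputs: same-sex crosses, empty populations, q outside
  [0,1], all-wins paired trials, and orange-male phenotype records all
  raise typed errors rather than propagating nonsense.
- Frequencies are validated to sum to 1 within 1e-12 per sex; the
  neutral recursion conserves allele frequency to better than 1e-14
  over 1000 generations.

## Known limitations

- The equilibrium magnitude is a calibration, not a prediction: with
  unpublished mating-success and fecundity inputs, only the qualitative
  regime structure is parameter-free.
- The analysis layer is deliberately descriptive (terminal-window
  means, per-phase deltas); mixed-model and segmented-regression
  inference on cage trajectories is out of scope.
- Heterozygote females carry a 10% fecundity cost by default, so the
  "recessive cost" idealization is only approximate under the default
  parameterization; a fully recessive variant (het fecundity 1.0) is a
  one-line config change and is exercised in the tests.
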