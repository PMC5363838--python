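# Methods

This note documents the models implemented in `tidemet`, the parameter
choices behind them, and their limitations.  It is written for a reader
who wants to judge what the package's numbers do and do not mean.

## Stoichiometric conventions

Compounds carry an elemental composition over C, H, O, N, S plus a net
charge (the dominant species at pH 7).  Reactions are maps from compound
ids to coefficients (negative = consumed); element and charge balance is
enforced to 1e-9 absolute on atom counts.  All fluxes are
mmol l⁻¹ day⁻¹; biomass is expressed per C-mol with the standard
composition CH₁.₈O₀.₅N₀.₂.

The degree of reduction uses the conventional heterotrophic valences —
C +4, H +1, O −2, N −3 (ammonium reference), S +6 (sulfate reference) —
with a charge correction:

    γ = (4·C + H − 2·O − 3·N + 6·S − charge) / C.

Thus glucose and acetate have γ = 4, formate 2, succinate 3.5, and
biomass 4.2.

Formation energies (ΔGf°′, 25 °C, pH 7) come from the classical
biochemical compilations.  Values for tyrosine, histidine and methionine
are approximate (flagged in `library.py`); they supply ~10% of the feed
carbon, and sensitivity of the community-level results to them is small
because their catabolism is lumped (see below).  Temperature is fixed at
298.15 K; there is no ionic-strength or activity correction — the
package aims at community-bioenergetic bookkeeping, not geochemical
accuracy.

## Yield prediction

Every metabolic reaction is the sum of a catabolic half (one formula
unit of electron donor fully oxidized with a given acceptor couple, or a
fermentation with fixed product pattern) and an anabolic half
(assimilation of a carbon source into exactly 1 C-mol biomass, with
ammonium as nitrogen source).  Both halves are completed automatically
by solving element/charge conservation for the free coefficients (CO₂,
H₂O, H⁺, NH₄⁺, HS⁻, H₂ as appropriate); this keeps every shipped
reaction balanced by construction.

The halves are coupled through an energy balance: growth dissipates a
substrate-dependent amount of Gibbs energy per C-mol biomass,

    D = 200 + 18·(6 − C)^1.8 + exp[((3.8 − γ)²)^0.16 · (3.6 + 0.4·C)]  kJ/C-mol,

an empirical correlation in the carbon chain length C and degree of
reduction γ of the substrate (for substrate mixtures the mole-weighted
mean chain length and the C-mol-weighted γ are used).  The catabolic
multiplier is

    λ = (D + ΔG_an) / (η · (−ΔG_cat)),

and the yield Y is 1 C-mol biomass over the total organic C-mol the
balanced net reaction consumes.  A `dissipation_override` replaces the
correlation with a fixed value when tabulated dissipations are
preferred.

### Respiratory energy conservation

η is the fraction of the catabolic Gibbs energy that the catabolic
machinery delivers as usable energy.  For substrate-level (fermentative)
catabolism η = 1.  For respiration the package takes the view that the
cell can only use what its chain banks into the proton motive force:

    η = q · pmf / (2F · span)   (dimensionless, F absorbed in volt units)

with q the charges translocated per 2 electrons and span the redox
potential difference per 2 electrons.  The presets, at pmf = 180 mV:

| chain            | q  | span (V) | η    |
|------------------|----|----------|------|
| canonical        | 10 | 1.14     | 0.79 |
| bd-terminated    | 4  | 1.14     | 0.32 |
| denitrification  | 6  | 1.30     | 0.42 |

The canonical chain is NADH dehydrogenase + bc₁ + a proton-pumping
heme-copper oxidase over the NADH→O₂ span.  The bd chain loses the bc₁
and oxidase pumping because cytochrome bd accepts quinol electrons and
does not translocate protons.  The denitrification chain keeps complex I
and bc₁ but none of the nitrogen-oxide reductases pumps; its span is
NADH→NO₂⁻/N₂ (1.30 V from the shipped ΔGf°′ table).  The charge
stoichiometries are inferred, not measured, and are config-overridable.

This uniform discount is a deliberate design choice.  A bare
dissipation-correlation calculation cannot distinguish denitrifying from
aerobic growth — per electron, the nitrite→N₂ couple is actually
*richer* than O₂ — and so would predict denitrifying acetate yields of
~0.47 C-mol/C-mol, far above what denitrifying cultures achieve.
Charging each reaction only the PMF-conserved fraction of its catabolic
energy reproduces the observed ordering and magnitudes: aerobic glucose
0.62, denitrifying acetate 0.30, glucose fermentation 0.14, formate
respiration 0.19.  The cost of uniformity is a mild double-counting for
aerobic growth (the correlation was calibrated largely on aerobic data),
which depresses the aerobic-glucose yield from 0.67 to 0.62 — within
the uncertainty of the anchor.  Electron-donor entry points below NADH
(formate, succinate, H₂) are not given their own charge stoichiometries;
they reuse the preset of their acceptor branch.

## The default reaction network

The shipped network (letters a–v, 22 reactions) is a reconstruction of
the community's metabolism from its measured conversions and
per-population gene activities, not a genome-scale model:

* **r** glucose fermentation to acetate + formate + H₂ (bin D, *Vibrio*);
* **s** alanine+serine co-fermentation to the same products (bin F,
  Firmicutes) — alanine fermentation alone is endergonic at standard
  conditions, so the two are lumped in feed proportion, mimicking
  Stickland-style coupling;
* **t, u** fermentation of the remaining amino acids (glutamate,
  aspartate, tyrosine, histidine, methionine, as one feed-proportion
  mixture) to succinate, ammonium, sulfide and a little H₂ (bins F, D);
* **d–g** aerobic respiration of succinate, acetate, formate and H₂ by
  bins A–B with the canonical (cbb₃-type) chain;
* **h–j** nitrite → N₂O on succinate/acetate/formate (bin A);
* **k–l** nitrate → nitrite on formate/H₂ (bins B, D);
* **m–n** N₂O → N₂ on formate/H₂ (bins B, C);
* **o** incomplete sulfide → S⁰ oxidation (bin C), **p** sulfate
  reduction with H₂ (bin E);
* **q** formate oxidation with O₂ through the non-pumping bd oxidase
  (bin D) — the low-yield oxygen elimination route;
* **v** storage of glucose as a glucan, assigned to no population;
* **a–c** the "sorted" alternative: canonical respiration of the
  complete feed carbon mixture with O₂, nitrite and nitrate (bin A).

The unsorted scenario comprises d–v, the sorted scenario a–c.  H₂- and
sulfide-oxidizing reactions assimilate acetate (mixotrophy); all other
reactions assimilate their own catabolic substrate.  ¹⁵N isotope
channels are collapsed to bulk N₂/N₂O, since labels do not alter
stoichiometry.

## Community flux fitting

The fit solves min ‖W(Sv − observed)‖² + ε‖v‖² with v ≥ 0 by
non-negative least squares (scipy's NNLS on the ridge-augmented system).
S is the net stoichiometric matrix over the *observed* compounds only;
compounds absent from the observation vector (CO₂, H₂O, H⁺, NH₄⁺,
biomass and storage by default) are free outputs.  Weights default to
1/|observed| with a floor of 1% of the largest observed rate, so that
compounds observed at zero net conversion (the cross-fed intermediates)
are strongly enforced.  ε = 1e-8 merely tie-breaks underdetermined
networks; the reported solution is the minimal-norm member of the
optimal family, and the residual is always reported alongside.  Two
reactions with identical net stoichiometry (t and u) are intentionally
degenerate and receive equal flux, splitting that growth between bins D
and F.

Derived quantities: per-population growth sums rate × biomass
coefficient over each bin (storage excluded); abundances are growth
fractions; the community yield is biomass C-mol produced per organic
C-mol with net consumption (CO₂ and storage are not organic substrates,
and cross-fed intermediates cancel at net zero).

### The reference observation vector

`paper_conversions()` encodes the steady-state behaviour of the
chemostat as a conversion vector: all nine carbon substrates and both
nitrogen acceptors fully consumed at supply rate (concentration × 0.26
day⁻¹), nitrite+nitrate denitrified to N₂ (2.73 mmol N₂ l⁻¹ day⁻¹),
oxygen consumption equal to the pulse regimen's supply (20 ml min⁻¹ ×
5 min × 2/day at 25 °C into 2.8 l = 2.92 mmol l⁻¹ day⁻¹ — an upper
bound on availability, and a good estimate of use since oxygen is
depleted between pulses), zero net accumulation of formate, succinate,
H₂ and N₂O over a cycle, and all sulfur (sulfate plus methionine-S)
leaving as elemental sulfur.  Growth is left free, so the fitted
community yield (~0.31 C-mol/C-mol) is a prediction of the network's
energetics, not an input.  Under these conditions the electron surplus
of the feed over the available acceptors is absorbed by the storage
reaction (~4.2 C-mmol l⁻¹ day⁻¹), consistent with a community that
stores carbon during the anoxic phase.

## Diffusion physics

The oxygen flux toward a suspended cell or aggregate is the quasi-steady
spherical-shell solution with a finite boundary layer,
J = 4πD·(rR/(R−r))·(C_bulk − C_surf), with D = 1e-9 m² s⁻¹ and
R = 10 μm (the Kolmogorov scale) by default; R→∞ recovers 4πDrΔC.  The
depletion threshold sets C_surf = 0 and solves for the bulk
concentration at which supply equals demand.  The default
protein-per-cell (5.2e-14 g) is back-calculated so that 20 mmol O₂ g⁻¹
protein h⁻¹ corresponds to 25 fmol cell⁻¹ day⁻¹ for a 1-μm cell, and is
overridable.  Aggregates are treated as point sinks with N× the
single-cell uptake; there is no intra-aggregate reaction–diffusion
profile, so thresholds for large dense aggregates are conservative
(underestimated).

## Omics normalizations

Per-ORF transcriptional activity is (reads/length) divided by the bin's
(total reads/total length), making 1.0 the bin-average activity; the
ORF-length-weighted mean per bin is exactly 1 by construction, which the
tests assert to 1e-12.  Functional-gene counts are divided by the rpoBC
count (a conserved single-copy gene); both raw and bd-I+bd-II-summed
outputs are available since the environmental survey may plot either.
Activities are reported to 3 decimals in the CLI.  Upstream read
mapping, HMM scanning and e-value filtering are out of scope — the
package consumes count tables.

## The chemostat simulator

`simulate_cycle` integrates mass balances (inflow − outflow −
consumption + production) for O₂ (liquid and a recirculated headspace
reservoir), NO₃⁻, NO₂⁻, N₂O, N₂, glucose, acetate, formate, succinate,
an amino-acid pool, elemental sulfur and biomass over repeated 12-h
cycles, with LSODA at rtol 1e-8 and the pulse discontinuities aligned to
integration breakpoints.  Monod kinetics with no cross-inhibition are
the default ("braided" null model: every process runs whenever its
substrates are present); `redox_tower=True` suppresses the anaerobic
processes above an O₂ threshold, giving the contrasting hypothesis.

What the generator emulates: the ~2-h transient oxygen window after each
pulse (the pulse fills the headspace, and donor-limited community uptake
plus venting drain it), transient formate/S⁰ accumulation during the
oxic phase, continuous denitrification, and a positive cumulative
electron balance (donors supplied outpacing acceptors) within a cycle.
What it does not emulate: true uptake kinetics (the Vmax/Ks values are
not measured; they were chosen once so that the default run reproduces
the ~2-h oxygen window and plausible steady concentrations), isotope
mass channels, aggregate-scale spatial structure, and population-level
competition (biomass is one pool).  Passing simulator-based tests
therefore demonstrates internal consistency of the mass balances, not
predictive kinetics.

Seeded Gaussian measurement noise is applied to the output trajectories,
never inside the integrator, so a fixed seed gives bit-identical output.
The observation and count generators are likewise pure functions of
(parameters, seed): S·v* plus relative noise for conversion vectors, and
per-bin multinomial draws with probability ∝ activity × length for read
counts.

## Numerical choices and degenerate inputs

* Balance tolerance 1e-9 absolute; fit determinism from NNLS on fixed
  matrices; ridge ε = 1e-8.
* All-zero observation vectors return a zero-rate result with a warning;
  yield and abundances raise on zero carbon consumption / zero growth.
* Endergonic catabolic halves are rejected ("not a catabolism"), as are
  couplings whose anabolic half would release more energy than is
  dissipated (negative λ).
* Zero-length or duplicate ORFs are rejected at load; bins with zero
  reads are skipped with a warning.
* Chain efficiencies above 1 are reported with a warning rather than
  capped silently.

## Problem sizes

The default analyses are desk-scale by design: a 22-reaction network
over ~27 compounds, simulations of 2 tidal cycles at 60 points/hour, and
synthetic count tables of 40–50 ORFs at 1e5–1e6 reads.  The full test
suite runs in well under a minute on one CPU.

## Known limitations

* The reaction set is a reconstruction; alternative lumpings of the
  amino-acid fermentations would shift the fitted abundances (much less
  so the community yield, which is pinned by the electron and energy
  budgets).
* The respiratory charge stoichiometries behind the efficiency presets
  are inferred from textbook complex properties, not measured for these
  organisms.
* The community yield from the reference fit depends on the assumed
  oxygen consumption (the printed supply regimen); if substantially less
  of the pulsed oxygen dissolved, more electrons would flow to storage
  and the predicted yield would fall.
* Sulfate is nearly absent from the feed (0.01 mM), so bin E
  (*Desulfovibrio*) receives essentially zero fitted growth; its
  presence in the real community likely reflects micro-niches the bulk
  model does not resolve.
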