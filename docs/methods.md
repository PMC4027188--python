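# Methods

## The reaction being modelled

Mariner-family transposons (the human Hsmar1 element is the example
implemented here) excise from a donor plasmid by a cut-and-paste reaction.
A transposase dimer synapses the two 30-bp inverted-repeat ends into a
transpososome and then makes four single-strand breaks: at each end the
non-transferred strand (NTS) is nicked first, a few nucleotides inside the
element, and the transferred strand (TS) is cut second, exactly at the
junction, exposing the 3'-OH that is later joined to a target site.  There
is no hairpin intermediate; the two cuts at an end are independent
hydrolysis events, and the NTS-before-TS order at a given end is taken as
a hard constraint of the state space, not something the model can violate.

The open mechanistic question is how the *two ends* are coordinated.
Three candidate mechanisms are implemented as continuous-time Markov
chains over per-molecule states (synapsis phase, per-end cleavage status
U/N/D, and, where relevant, a conformational-transition flag):

* **independent** — each end nicks and completes its TS cut on its own
  schedule (11 reachable states);
* **sequential** — the double-strand break is completed at one end before
  chemistry starts at the other (10 states);
* **constrained** — both NTS must be nicked, and a single coordinated
  conformational transition must occur, before either TS is cut
  (10 states, with the doubly-nicked state split into pre- and
  post-transition forms).

Synapsis is irreversible and pseudo-first-order: the assay conditions keep
transposase in excess over the plasmid substrate (20 nM vs 6.7 nM), and
nicking requires prior synapsis.  Integration is a single lumped absorbing
step that joins both transposon 3' ends to a target; its internal topology
(inter- vs intra-molecular, target choice) is out of scope.

## Rate parameters and calibration

All rate symbols are defined by this package — the underlying experiments
are gel time courses, not rate equations.  `RateSet` holds five
first-order constants (s⁻¹): `k_syn` (synapsis), `k_nts` (NTS nick, per
end), `k_trans` (coordinated transition; constrained mechanism only),
`k_ts` (TS chemistry, per end) and `k_int` (lumped integration).

Defaults are calibrated, by exact root finding on hypoexponential survival
curves, to the two half-lives reported for this reaction: supercoiled
substrate consumption (synapsis plus first nick) t½ = 30 s, and TS
cleavage t½ = 15 min.  Two apportionments inside those totals are free
choices and are fixed as follows:

* **Synapsis dominates SC consumption** (95% of the mean waiting time,
  i.e. `k_syn ≈ 0.025 s⁻¹`, `k_nts ≈ 0.24 s⁻¹`).  Rationale: nicking
  requires synapsis and bimolecular synapsis is inefficient, which is why
  a substrate pairing a wild-type end with a nicking-dead mutant end is
  consumed at the wild-type rate.  An even 50:50 split would make that
  substrate ~1.5× slower, contradicting the observed kinetics.
* **The coordinated transition limits TS cleavage** (`k_ts = 10·k_trans`,
  giving `k_trans ≈ 8.7e-4 s⁻¹`).  Rationale: the long NTS-to-TS delay is
  attributed to the conformational reorganisation between the two
  hydrolysis events, not to slow TS chemistry itself.
* `k_int = k_ts`; integration kinetics are not analysed.

## Mutant presets

Transposon-end variants act multiplicatively on the rates at their own
end: `nts_factor` on nicking, `ts_factor` on TS chemistry, and a
`competence` in [0, 1] that enters the coordinated transition through a
coupling rule (`additive` — the wild-type rule, giving half-site rescue;
`multiplicative`; or `min`).  The gels behind these phenotypes are
qualitative, so the factor values are package choices fixed once to
reproduce the observed rank order:

| variant class            | nts | ts  | competence | observed phenotype encoded |
|--------------------------|-----|-----|------------|----------------------------|
| WT                       | 1   | 1   | 1          | complete reaction          |
| 5G (positions −2..+3)    | 1e-5| 0.01| 0.05       | near-inert; SC persists for hours; paired with WT, stalls at the singly-nicked state because the constrained pathway needs both nicks |
| −1 flank mutants         | 1   | 0.3 | 0.01       | nicking normal, almost no excision alone, rescued by a WT partner end |
| +1C, +1G, +2G            | 0.5 | 0.2 | 0.5        | mild nicking defect plus transition defect |
| other +1/+2/+3/+4        | 1   | 0.5 | 0.8        | mild TS-cleavage defect    |
| −2 flank mutants         | 1   | 0.9 | 0.9        | nearly wild type           |

Transposase variants multiply `k_syn`, `k_trans` and `k_ts` globally and
may override the coupling rule: W118R (hyperactive) = 5× synapsis, 0.5×
transition, multiplicative coupling (its rescue of a −1T end by a WT
partner fails because the coupled rate collapses to the product of
competences); V119G (hypoactive) = 5× synapsis, 0.05× transition (stalls
after nicking).  The data cannot apportion the −1 defect between
competence and TS chemistry; both knobs are exposed and the default splits
it (competence 0.01, ts_factor 0.3).

## Simulation

The master equation of each CTMC is solved exactly by matrix
exponentiation over the sampling grid (the default grid mimics kinetics
lanes: 0, 15 s, 30 s, 1–180 min); an exact Gillespie sampler over the same
generator provides per-molecule trajectories and finite-count noise.
Cross-checks: the deterministic solver agrees with a stiff LSODA
integration to <1e-8; a 50 000-molecule Gillespie run agrees with the
master equation to <0.01 in every species fraction; mass is conserved to
1e-9 and the integrated state is monotone.

Half-lives are read from time courses by monotone linear interpolation
(`half_life`) or computed exactly by root finding on the propagated
distribution (`species_half_life`).

## Virtual gels

Native-gel classes are assigned structurally: SC (no breaks), OC (nicked),
LIN (single-end break, SEB), BB+ETF (double-end break) and integration
products.  For denaturing gels, strand breaks are placed on a circular
coordinate map (1-based; boundary *k* is the phosphodiester between bases
*k* and *k+1*; the element occupies bases 1..E).  Because the ends are
inverted repeats, NTS and TS swap physical strands between the two ends;
each strand of the excised fragment therefore carries a junction (TS)
terminus at one end and a recessed (NTS, default 3 nt) terminus at the
other, so both strands are E−3 nt.  The restriction digest is modelled as
a blunt double-strand cut at one backbone coordinate (the enzyme's few-nt
stagger is below gel resolution) whose 3' termini are flagged for fill-in
labelling.  Labelling rules: 5'-kinase marks every linear single-strand
fragment once; 3'-fill-in marks only fragments whose 3' terminus is a
restriction cut — which is why the excised transposon itself takes no
fill-in label.  Band intensity is molar abundance × label count; bands
merge when their relative length difference is below a configurable
tolerance whose default is 0 (only exactly co-migrating, i.e.
equal-length, strands merge).  A tolerance of 0 keeps the diagnostic SEB
pattern countable: the purified SEB digest fragment denatures into three
equal-intensity strands when the partner end carries its NTS nick
(2497/1497/1003 nt with the default geometry) and two strands (2500/2497
nt) when it does not.

The default plasmid geometry (element 1500 bp, backbone 2500 bp, digest
site 1000 bp from the right junction) is invented plumbing — the real
plasmid's map is not published — and is configurable; the only constraint
that matters is the ≥500-bp asymmetry of the two junction-to-site arcs,
which lets SEB-Left and SEB-Right resolve on the native gel.

## Synthetic data and what it does (not) capture

`synthetic_data.generate` produces tidy quantified-lane tables: native
class fractions per time point (and the SEB partner-nick probability where
SEB mass exists), times replicates, each multiplied by `exp(ε)`,
ε ~ N(0, σ²) independent per band/time/replicate (default σ = 0.15,
a plausible densitometry error; 3 replicates, a typical gel experiment),
optionally renormalised per lane.  This captures multiplicative
densitometry noise and finite-molecule noise (via the Gillespie option)
but not lane-loading artifacts, background subtraction errors, partial
digestion/labelling, or correlated errors within a lane — so passing
benchmarks show identifiability under the assumed error model, not
robustness to every real-gel pathology.

## Inference

Fits maximise a Gaussian likelihood on log(intensity + 1e-4), matching the
lognormal generator, over log10-rates with L-BFGS-B from multiple starts
(the calibrated defaults plus Latin-hypercube points; deterministic given
a seed).  AIC (= 2k − 2·lnL, counting the noise scale) ranks mechanisms;
they are non-nested, so no likelihood-ratio test is attempted; ties break
by BIC, then parameter count.

Mechanism selection frees only the parameters shared by all candidates
(`k_nts`, `k_ts`), holding `k_trans` at its calibrated value for the
constrained candidate.  This choice is load-bearing: if `k_trans` is also
freed, the constrained model approaches its fast-transition limit, which
single-substrate wild-type kinetics cannot distinguish from the
independent mechanism (best-fit RMS log-residual ≈ 0.02, far below a
σ = 0.1 noise floor).  That degeneracy is the model-space restatement of
why the strand-analysis (partner-nick) and mutant-crosstalk experiments
were needed in the first place; with the shared parameterisation the
benchmark discriminates both directions with AIC margins in the hundreds.

Phenotype classification uses configurable thresholds on the end-point
supercoiled fraction, peak nicked fraction, end-point SEB fraction and the
end-point *excision yield*.  The yield is defined as double-end-break plus
integrated mass: on a gel the released backbone persists after the excised
fragment integrates elsewhere, so the backbone band reports cumulative
excision.

## Problem sizes used in the shipped benchmarks

Reported results use: 50 000 molecules for the SSA/master-equation check,
1 000 random cut maps for the fragment-walk cross-validation, and 20
seeded datasets (σ = 0.1, 3 replicates, 12-point grid) per generating
mechanism for the discrimination benchmark.  These sizes give comfortable
statistical margins (binomial and Monte-Carlo) while keeping a full run in
the minutes range on one CPU.

## Known limitations

* No reversible binding, no transposase-concentration dependence beyond
  the pseudo-first-order synapsis rate, no temperature dependence.
* Integration is a lumped absorbing step; single-end strand-transfer and
  other aberrant products are not modelled.
* End variants are symbolic (name + mutated positions + factors); factor
  values are configuration, not predictions from sequence.
* Gel migration physics is cosmetic (log-length ASCII rendering only);
  incomplete digestion or labelling is not modelled.
* The 30 s / 15 min calibration derives from kinetic measurements made
  under possibly different conditions; it is a default, not a fit to any
  lane quantification.
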