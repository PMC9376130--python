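# Methods

## The decision problem

Shenzhen's current newborn-screening program detects phenylketonuria
(PKU) with an immunofluorescence (IF) assay; the other eleven inborn
errors of metabolism (IEMs) of China's nationally recommended tandem
mass spectrometry (MS/MS) panel go undetected until they become
symptomatic. `nbscea` evaluates replacing this with MS/MS screening of
all 12 IEMs — PKU, MSUD, CIT-I, CIT-II, HCY, MMA, IVA, GA-I, PA, PCD,
MCAD and VLCAD — from a societal perspective, in 2018 RMB.

The model is a decision tree (the screening stage) feeding per-disease
Markov cohort models (the lifetime stage). A birth cohort of 200,000
newborns is followed for 82 one-year cycles, the average life
expectancy of Shenzhen residents in 2018. Costs and quality-adjusted
life-years (QALYs) are both discounted at 3% per year; the
cost-effectiveness threshold is three times per-capita GDP,
3 × 189,568 = 568,704 RMB/QALY.

## Screening stage (decision tree)

Assay performance is applied with expected-value (fractional-mass)
arithmetic, never integer sampling: the outputs of interest are
deterministic expectations. IF has sensitivity 100% and specificity
78.6%; MS/MS has both at 100%. One blood sample covers the whole MS/MS
panel, so the 296 RMB sample fee is charged once per newborn regardless
of panel size; the IF comparator charges its 23 RMB fee for PKU only.
Every screen-positive newborn (true or false) receives one confirmation
test (319 RMB after IF, 296 RMB after MS/MS). False positives then exit
the model with no further costs — the confirmatory test is treated as
perfect. We deliberately do not charge false positives a transport
episode: sampling and recall happen through the maternity hospital, and
with a 21.4% IF false-positive rate such an episode would add ~93 RMB
to every status-quo newborn and distort the comparison between
programs. Program overheads (fixed costs of 1.222M RMB/year spread over
the cohort, plus 4.33 RMB/person-year of utilities and administration)
are charged to any operating program.

## Lifetime stage (Markov cohort model)

Each disease has its own state set: alive without sequela (NS), one
state per sequela in the disease's set — development delay (DD),
neurological damage (ND), mental retardation (MR), renal damage (RD) —
and dead. Sequela states are mutually exclusive and absorbing-but-for-
death: there are no inter-sequela transitions, matching the premise
that a child occupies exactly one health state per cycle and that
transitions are memoryless. Detected newborns follow the *screened*
course (treated from birth); undetected ones follow the *unscreened*
course.

Within a cycle, competing risks compose sequentially: death first —
disease-specific and background mortality combined as independent
hazards, `1-(1-p_dis)(1-p_bg)` — then sequela onset among survivors.
This guarantees stochastic rows without probability overflow. Cohort
mass is checked every cycle to 1e-9.

Person-time uses the trapezoid half-cycle correction (the average of
start- and end-of-cycle occupancy). Consistently, accruals are
discounted at mid-cycle, `(1+r)^-(k+0.5)`; an end-of-cycle switch
(`econ.discount_timing: end`) exists for sensitivity work. The
correction applies to both cost and QALY accrual.

Costs per person-year: detected patients accrue age-banded disease
treatment (the bands split at age 5, reflecting the extra care young
symptomatic children need), follow-up visits (4/year; 1,184 RMB on the
MS/MS program, 1,276 on IF), family transport (435) and lost
productivity (3,060) while alive; sequela states add the sequela-care
cost (DD 3,064; ND 53,400; MR 12,000; RD 70,213). Undetected patients
accrue nothing until symptomatic, which by default means entry into a
sequela state (`econ.unscreened_cost_onset: sequela`; a fixed onset age
is configurable), and never accrue screening-program follow-up visits.
Utilities: healthy newborns 1.0; diseased NS 0.900; DD 0.843; ND 0.840;
MR 0.790; RD 0.670; dead 0. The same sequela has the same utility
across diseases.

## Strategy evaluation, ranking, ladder

A strategy's per-newborn cost C and effectiveness E mix the healthy
cohort (background mortality only, utility 1), screened diseases'
screened arms and unscreened diseases' unscreened arms by incidence,
plus the year-0 screening stage. ICER = ΔC/ΔE; comparisons with
|ΔE| < 1e-12 are reported as undefined. Dominance is flagged but never
used to exclude strategies.

The single-disease ranking evaluates MS/MS screening of each non-PKU
disease alone against not screening it, holding everything else fixed;
a single-disease program bears the full 296 RMB sample fee, which is
why every single-disease ICER exceeds the threshold while combined
panels do not. Ties break alphabetically; undefined ICERs rank last.
The strategy ladder then adds diseases to the PKU base in ascending
ICER order — strategy k screens PKU plus the top k diseases with one
shared MS/MS sample — and compares each rung against the status quo.

## Sensitivity analyses

The discount sweep re-runs the base-case comparison at 0–10% in 1%
steps (11 points, both endpoints included), re-discounting costs and
effects alike. The tornado perturbs one parameter at a time: disease
incidences ±50%, costs ±10% (age-banded treatment costs and the program
cost move jointly as groups), utilities to their published bounds.
Entries are sorted by ICER-interval width, ties alphabetical by
parameter path; every run works on a deep copy, and restoration is
verified by content hash.

## Budget impact analysis

The BIA takes the Shenzhen government's standpoint, undiscounted
(budget-holder convention), 2019–2028, with a fresh 200,000-newborn
cohort each year. The screening line is cohort × sample fee × the 80%
government share — exactly 47.36M RMB/year for MS/MS and 3.68M for IF;
program overheads and family-borne shares are outside the budget lines.
The treatment line cumulates over birth cohorts tracked at their actual
ages: surviving patients' annual treatment plus sequela care × the 60%
government share, using the screened arm for screened diseases and the
unscreened (symptomatic-onset) arm otherwise. Diseases whose untreated
course kills within the first two years are excluded from the treatment
line; by default the exclusion set is derived from the course library
(2-year cumulative unscreened mortality > 50%, which flags MSUD only),
and an explicit per-disease `early_death_flag` overrides it. Flag
choices materially change the treatment line, so they are recorded in
the run manifest via the parameter hash.

## The synthetic course library

Published age-specific mortality and sequela-onset curves for these 12
IEMs in screened vs unscreened children are not available to this
package, so `course_synthesis` generates deterministic stand-in curves
from compact templates: an annual death probability for ages 0–1 and
for ages ≥ 2, plus constant annual sequela-onset probabilities inside
an onset window (ages 0–4). Unscreened arms carry excess late mortality
too — untreated symptomatic disease keeps killing beyond infancy —
which simultaneously costs QALYs and caps how many years of expensive
sequela care undetected patients accrue.

The template values were calibrated once, against the engine at the
baseline settings, to two anchors and then frozen (version 1):

* the **per-case discounted QALY gain** of screening each disease
  matches the gain implied by the published single-disease
  cost-effectiveness table (its incremental QALYs divided by the
  disease's incidence) — e.g. ≈7 QALYs/case for PCD, ≈19 for MSUD,
  ≈2.2 for HCY;
* the **screened arm costs at least as much** as the unscreened arm for
  every disease (lifelong treatment of survivors exceeds the shorter,
  sequela-gated costs of undetected patients), matching the sign of
  every published single-disease cost increment.

With these anchors the full pipeline reproduces the published
qualitative structure: the single-disease ICER order (PCD best, VLCAD
worst), a strategy ladder that decreases monotonically with only its
first rung (PKU+PCD) above the threshold, a headline ICER below the
threshold, a tornado led by P_PCD, P_MMA and C_MSScr with no single
perturbation crossing the threshold, and a ~490M RMB decade budget.
The curves are *not* natural-history estimates: absolute per-disease
survival and onset trajectories, and any age structure beyond the
two mortality bands and the onset window, carry no evidential weight.
A transcription of real age-specific curves can replace the packaged
library through the tabular course-library format (columns
`disease, arm, age, p_death_disease, p_onset_<sequela>`), at which
point results inherit the data's fidelity.

Background mortality is a two-parameter form — a flat 5×10⁻⁵ annual
rate to age 60, then a Gompertz ramp `1e-4·exp(0.20·(age−60))` —
fitted once so a healthy cohort traced through the engine over the
truncated 82-cycle horizon has an undiscounted life expectancy of
~81.7 years, the only printed anchor. It applies identically to both
arms and to healthy newborns.

## Numerical and reporting conventions

All arithmetic is double precision; cohort-mass conservation tolerance
1e-9; effectiveness-increment epsilon 1e-12. Reported tables round E
and C to 3 decimals, ICERs to integers, and budget lines to 2 decimals
(million RMB); internal values stay unrounded. Repeated runs are
bit-identical — the model contains no randomness; the only stochastic
code in the project is the individual-level microsimulation used as an
independent cross-check of the cohort engine.

## Design choices where the convention was open

* **Discounting of effectiveness.** Both costs and QALYs are
  discounted at the 3% base rate. Under this convention a newborn's
  QALE is ~30 discounted QALYs (not ~74–82 undiscounted years), and
  the discount sweep is steeper than it would be if only costs were
  re-discounted: the base-case ICER crosses the threshold between 5%
  and 6%.
* **CIT-II incidence.** No published incidence row exists; the
  baseline assumes CIT-I's value (3.76×10⁻⁶), flags it
  `incidence_assumed: true`, and shares CIT-I's jointly printed
  treatment costs. Users may override both.
* **PKU treatment cost** (15,000 RMB/year, field investigation) is
  applied flat across both age bands, since a single value is printed.
* **Follow-up visits** accrue only to patients detected by a screening
  program; clinically diagnosed (unscreened) patients accrue treatment,
  sequela care, transport and lost productivity but not the screening
  program's visit schedule.

## Limitations

The synthetic course library constrains what passing results can show:
the package demonstrates a correct, internally consistent modelling
pipeline whose outputs reproduce the published *structure*, not
re-estimated natural histories. Tunnel states, time-in-state-dependent
transitions, probabilistic sensitivity analysis, net monetary benefit,
currency conversion and assay operational effects (turnaround, recall)
are out of scope.
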