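# Methods

## Model formalism and assumptions

Every reaction obeys mass-action kinetics: the net flux of a reaction
with reactant stoichiometries n_i and product stoichiometries m_j is
v = kf·∏[S_i]^{n_i} − kr·∏[P_j]^{m_j}, the reverse term present only for
reversible reactions. Total reactant stoichiometry is restricted to one
or two (elementary uni/bimolecular steps); no Michaelis–Menten or Hill
terms are admitted anywhere, including on import from SBML. Units are
fixed package-wide — concentration μM, time s, first-order constants
s⁻¹, second-order constants μM⁻¹s⁻¹ — with no conversion layer, and a
single dimensionless compartment of size 1.

Clamped inputs (the tamoxifen dose, the basal EGF medium, synthesis
pools) are *boundary species*: they remain in the state vector but
receive a zero derivative, so treated and untreated model variants share
one state layout and one stoichiometry matrix. Rules follow SBML
semantics: assignment rules are evaluated before flux computation at
every right-hand-side call and their targets are excluded from
integration; rate rules override the stoichiometric derivative of their
target.

Conserved moieties are computed as an integer basis of the left null
space of the stoichiometry matrix restricted to non-boundary, non-ruled
species, using exact rational elimination (sympy) to avoid
floating-point rank decisions; each basis vector is scaled to coprime
integers with non-negative sum.

## The packaged network

The packaged reaction and species tables
(`data/sm1_reactions_synthetic.tsv`, `data/sm1_species_synthetic.tsv`)
are a synthetic transcription authored for this package: a network with
exactly 128 species, 143 reactions (70 reversible → 213 rate constants)
and one rule, spanning the pathway modules a GPR30/EGFR crosstalk model
needs — tamoxifen→GPR30→G-protein→AC/PKA, Gβγ→PLC→IP₃+DAG→PKC,
Gβγ→Src→MMP→HB-EGF shedding, EGF→EGFR dimerisation and
autophosphorylation, Shc/Grb2/SOS→Ras→Raf→MEK→ERK with negative feedback
(ERK→SOS, PKA→Raf, Akt→Raf), PI3K→PIP₃→PDK1/Akt with PTEN opposition,
JAK/STAT with SOCS feedback, the GRK/β-arrestin internalization–
recycling cycle (including the β-arrestin-2 scaffold that phosphorylates
ERK directly), explicit MKP/MAPK and PP2A/MEK phosphatase complexes, and
an ERK-driven nuclear program (Elk1/Fos/AP-1/Myc and p53/Mdm2 with
pro-apoptotic Bax/PUMA → cytochrome c → caspase readouts). The single
rule is an assignment collecting all doubly-phosphorylated-ERK pools
into the readout species `ppERK_total`.

Rate constants and initial concentrations are the package's own
order-of-magnitude design (first-order 10⁻³–1 s⁻¹, second-order
10⁻³–1 μM⁻¹s⁻¹, protein pools 0.1–1 μM, lipid/precursor pools larger),
chosen so the network exhibits the qualitative biology it encodes:
negligible pathway activity without ligand, a basal EGF drive giving the
untreated condition a small but non-zero ERK response, and a strong
multi-route ERK response under 250 μM tamoxifen (the experimental LC50,
used as the treated input). Two designed features deserve note. First,
elementary steps other than degradations, lumped transcription/
translation steps and multi-product dissociations carry small reverse
constants (microreversibility); reverse constants that would leak
activity into active states with no stimulus are kept at ~10⁻⁸ —
during design, a 10⁻³ reverse rate on G-protein reassembly was enough to
switch the whole GPCR arm on with zero tamoxifen. Second, the
β-arrestin-2 scaffold gives ppERK a receptor-proximal activation route
that does not pass through MEK, which is what makes the ppERK readout
respond to the input both fastest and most strongly.

Observables are tag-based sums of species: ppERK is the sum of every
species containing doubly phosphorylated ERK (free, nuclear, and in
Elk1/p53/MKP complexes), ppMEK includes the PP2A-bound form, PI3K_active
includes receptor-docked PI3K.

## Numerical choices

Integration uses LSODA (stiff/non-stiff switching) with rtol 1e-6,
atol 1e-9 μM, on a uniform grid with default horizon 3600 s and 600
output points — one hour covers both the fast transient and the
sustained phase of ERK activation, and tightening rtol to 1e-9 changes
ppERK trajectories of the full model by under 0.01% of peak. Flux
evaluation treats negative integrator undershoot as zero concentration;
output values between −atol and 0 are clipped to 0, anything below −atol
is surfaced. Integration failures raise with the last successful time,
never truncate silently. Note that the local tolerance does not bound
global error: matching a closed-form solution to 1e-6 *relative*
accuracy over several time constants needs rtol around 1e-8 or better.

Sensitivity coefficients use central differences with delta_rel = 1%
(forward scheme available for step diagnostics), normalized as
S(t) = (Δy/Δp)·(p/y). Points where the baseline observable is below a
floor (default: the integrator atol) are masked. Two scalar summaries
are reported — max |S| over time and time-averaged |S| — but ranking
uses the **time average** as its primary key: the pointwise maximum of a
normalized coefficient is attained where y is barely above the floor
(the start-up transient), which makes it sensitive to the output-grid
spacing and the floor value rather than to the network; in full-model
experiments the max-based order flipped between floor choices while the
average-based order never moved. Ties break by max |S|, then name. A
perturbation target whose baseline value is exactly zero (e.g. the
tamoxifen input of the untreated model) has S ≡ 0 by convention, since a
relative perturbation of zero is a no-op.

Rate-constant fitting is least squares in log₁₀k (positivity is
structural), multi-start with log-uniform starts from a seeded
generator; the current model values always seed one start. A start
counts as converged on a positive scipy status; the best converged
residual wins, and per-start diagnostics are kept.

## Expression statistics

Phred quality defaults to the standard base-10 form Q = −10·log₁₀E
(E = 0.01 → Q20); a base-2 variant is selectable for compatibility with
sources that print the formula with log₂ — with base 2 a Q20 threshold
would correspond to E = 0.25, which is why base 10 is the default. Read
filtering applies three independent rules in order (adapter present;
>20% N bases; >50% of bases below Q20), charging each discarded read to
the first rule it violates. RPKM is computed exactly as
counts/(mapped·10⁻⁶ × length_kb). BH adjustment is the step-up
q_(i) = min_{j≥i}(m·p_(j)/j) capped at 1, order-preserving and
tie-safe; it is verified in the test suite against both a naive O(n²)
oracle and statsmodels. DEG calling BH-adjusts the supplied per-gene
p-values and labels direction by the sign of the log₂ fold change at
q < 0.01; upstream differential-expression p-values are inputs, not
recomputed. Enrichment is the one-sided upper-tail hypergeometric
p = P(X ≥ k) per term (scipy's distribution), BH-corrected across terms,
with the background defaulting to the supplied annotation universe.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); each derives
its own numpy generator from `SeedSequence([seed, generator_code])` so
fixtures for different stages compose deterministically from one base
seed.

- `random_network` emulates small mass-action networks with known
  stoichiometry and log-uniform rate constants in [1e-3, 1]; it anchors
  the right-hand-side oracle and SBML round-trip suites.
- `noisy_timecourse` emulates observable time courses with unit-mean
  multiplicative lognormal noise of a requested CV — measurement noise
  only, no model misspecification, no sampling jitter.
- `synthetic_counts` emulates a treated-vs-untreated RNA-seq design with
  negative-binomial counts (variance μ + d·μ², default dispersion 0.1)
  and planted log₂ fold changes. The default of two samples per group
  mirrors a two-biological-replicate design. Per-gene p-values come from
  the exact two-sided Mann–Whitney U test — a documented rank-based
  method requiring no external DE tool. Its granularity matters: at two
  samples per group the smallest attainable two-sided p is 1/3, so
  q < 0.01 calls are impossible at that depth; calibration and recovery
  studies therefore use ten samples per group, which the exact test
  resolves to p ≈ 10⁻⁵.
- `planted_enrichment` builds a background, random gene sets and a gene
  list in which the designated term is represented at exactly
  round(enrich_factor × its chance expectation) members (stratified
  draw, remainder uniform over non-members). A weighted-sampling variant
  was tried first and rejected: the planted overlap was too variable for
  the planted term to reliably attain the smallest p.

Passing tests on these fixtures demonstrate the statistical machinery
and the solver are correct and calibrated; they do not demonstrate that
the packaged network's rate constants describe real MCF-7 kinetics
(no main-text parameter values exist to fit), nor do the count
generators reproduce library-preparation artifacts, gene-length biases
or correlated genes found in real RNA-seq data.

## Known limitations

- The packaged network is a designed, synthetic transcription with the
  documented structure counts; its quantitative outputs (μM, seconds)
  are illustrative, and only qualitative claims (treated > untreated
  ppERK; ppERK most tamoxifen-sensitive) are asserted by tests.
- Deterministic ODEs only — no stochastic simulation, no compartments
  or spatial effects, no thermodynamic consistency enforcement.
- The SBML layer covers the mass-action fragment this package emits
  (one compartment, polynomial kinetic laws, assignment/rate rules);
  SBML packages (comp, fbc, layout) and general MathML are out of scope
  by design, and anything outside the fragment is rejected with a
  diagnostic naming the reaction.
- Local sensitivity only (finite differences); no global methods
  (Sobol, Morris) and no identifiability analysis.
- Gene-set enrichment treats terms as flat sets; no ontology-graph
  propagation.
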