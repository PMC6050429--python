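# gpersim

Mass-action ODE modeling of the GPR30/EGFR/PI3K/MAPK/STAT signaling
network in breast cancer (MCF-7) cells, with tools to compare tamoxifen-
treated and untreated conditions, rank observables by sensitivity to the
tamoxifen input, and run the downstream RNA-seq expression statistics
(Phred quality, read filtering, RPKM, Benjamini–Hochberg FDR, DEG calling,
hypergeometric gene-set enrichment).

Tamoxifen is best known as an estrogen-receptor antagonist, but it is
also an agonist of the G-protein-coupled estrogen receptor GPR30 (GPER).
Through GPR30 it can activate PLC/PKC signaling, transactivate EGFR via
the Src → MMP → HB-EGF axis, and thereby drive ERK — a route that links
tamoxifen to MAPK-dependent apoptosis rather than to estrogen blockade.
This package is aimed at systems biologists who want to simulate that
crosstalk quantitatively and at bioinformaticians who need the matching
expression-statistics toolchain with fully synthetic, ground-truth test
data.

## The model

The network is pure mass action. For every reaction the net flux is

    v = kf · ∏_i [S_i]^{n_i}  −  kr · ∏_j [P_j]^{m_j}   (kr only if reversible)

with concentrations in μM, time in seconds, first-order constants in s⁻¹
and second-order constants in μM⁻¹s⁻¹; for example the reversible Akt
membrane-recruitment step Akt + PIP₃ ⇄ Akt_m has
v = k₁[Akt][PIP₃] − k_r1[Akt_m]. The system evolved is dx/dt = N·v(x)
where N is the integer stoichiometry matrix; boundary species (clamped
inputs such as the tamoxifen dose) keep a zero derivative. The packaged
network — a synthetic transcription of the signaling pathway, authored
for this package — has 128 species, 143 reactions (70 reversible, hence
213 rate constants) and 1 assignment rule, covering GPR30/Gβγ/PLC/PKC,
Src/MMP/HB-EGF transactivation, EGFR/Shc/Grb2/SOS/Ras/Raf/MEK/ERK,
PI3K/PDK1/Akt/PTEN, JAK/STAT, and the GRK/β-arrestin receptor
internalization cycle. The treated and untreated conditions share this
structure and differ only in the clamped tamoxifen input (250 μM vs 0).

Normalized local sensitivities S(t) = (∂y/∂p)·(p/y) are estimated by
central finite differences; observables are ranked by time-averaged |S|.
Expression statistics implement the standard formulas: Q = −10·log₁₀E
(base 2 available), RPKM = reads / (mapped reads in millions × exon
length in kb), BH step-up q-values with DEG calls at q < 0.01, and
upper-tail hypergeometric enrichment p = P(X ≥ k).

## Worked example

```python
from gpersim import full_model, Observable, compare_conditions
from gpersim.sensitivity import rank_sensitivities

untreated = full_model("untreated")
treated = full_model("treated")
pperk = Observable.from_tag(treated, "ppERK")

cm = compare_conditions(untreated, treated, pperk)
print(f"ppERK peak:  untreated {cm.untreated.peak:.3f} uM, "
      f"treated {cm.treated.peak:.3f} uM (ratio {cm.peak_ratio:.2f})")

names = ["Raf1_active", "PI3K_active", "ppMEK", "ppERK"]
ranking = rank_sensitivities(
    treated, [Observable.from_tag(treated, n) for n in names], "TAM")
for rank, (name, res) in enumerate(ranking, 1):
    print(f"{rank}. {name:12s} time-averaged |S| = {res.mean_abs:.5f}")
```

prints

```
ppERK peak:  untreated 0.133 uM, treated 0.445 uM (ratio 3.35)
1. ppERK        time-averaged |S| = 0.00848
2. ppMEK        time-averaged |S| = 0.00505
3. PI3K_active  time-averaged |S| = 0.00400
4. Raf1_active  time-averaged |S| = 0.00188
```

Tamoxifen stimulation roughly triples the ppERK peak (the one-hour AUC
rises about nine-fold), and among the four readouts ppERK is the most
sensitive to the tamoxifen input — the doubly phosphorylated ERK pool
sits at the bottom of a two-tier dual-phosphorylation cascade and also
receives the receptor-proximal β-arrestin-2 scaffold route, so relative
perturbations of the input are amplified most strongly there.

A command-line layer mirrors the library:

```bash
gpersim build --condition treated --out treated.xml
gpersim simulate --model treated.xml --obs ppERK --out traj.tsv
gpersim compare --untreated untreated.xml --treated treated.xml --obs ppERK
gpersim sensitivity --model treated.xml --obs ppERK,ppMEK,Raf1_active,PI3K_active \
    --perturb TAM --out sens.tsv
gpersim synth counts --seed 1 --out fixtures/
gpersim degs --stats fixtures/stats.tsv --q 0.01 --out degs.tsv
```

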