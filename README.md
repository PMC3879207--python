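# crmgrammar

Tools for studying the *motif grammar* of developmental enhancers:
how the number, spacing and orientation of transcription-factor (TF)
binding motifs inside a cis-regulatory module (CRM) determine the
robustness of its activity, tissue by tissue.

The package covers the full computational arc of a synthetic-enhancer
study in *Drosophila* embryos:

1. **Design** (`crmgrammar.motifs`, `crmgrammar.io`) — trim position
   weight matrices (PWMs) by information content, extract the best-fit
   motif instance per TF, optimize "neutral" spacer sequences that
   minimize inadvertent binding sites (including sites straddling the
   motif/spacer junctions), and assemble annotated CRM sequences
   (FASTA + BED6).
2. **Quantification** (`crmgrammar.quantify`) — score two-channel embryo
   images (tissue marker + CRM reporter): morphological background
   subtraction, tissue segmentation, mask cleanup, per-domain scoring, and
   the two robustness metrics with bootstrap errors:
   * **penetrance** — fraction of embryos with any tissue-overlapping CRM
     activity;
   * **expressivity** — mean fraction of the four scored tissue domains
     active within an embryo.
3. **Modelling** (`crmgrammar.occupancy`) — a fractional site occupancy
   (thermodynamic) model of CRM activity with distance- and
   orientation-dependent TF cooperativity, fitted to penetrance and
   expressivity, validated by leave-two-out cross-validation, and used to
   predict shortened CRMs and motif-number response curves.
4. **Simulation** (`crmgrammar.simulate`) — a generator for synthetic
   scoring tables and embryo images with known ground truth, used to
   exercise and validate every stage without external data.

## The model

Each of the `n` motif sites of a CRM is bound or unbound; all `2^n`
binding configurations receive statistical weights. A bound pMad site
contributes base weight `a0`, a bound Tin site `b0` (the unbound state has
weight 1; `a0 = b0 = 1` by default and are not fitted). Cooperativity
between adjacently bound pMad and Tin is geometric: each bound protein
carries a spherical "interaction space" of radius `r`, and for an
edge-to-edge motif gap `d` the overlap fraction is the normalized lens
volume

    omega(d, r) = (4r + d)(2r − d)^2 / (16 r^3)   for d < 2r, else 0.

The radius depends on the Tin motif orientation (`r_sense`,
`r_antisense`). An interacting pair multiplies the configuration weight by
`1 + (q1 − 1)·omega`; the higher-order model variant additionally applies
`1 + (q2 − 1)·min(omega_left, omega_right)` to every contiguous bound
pMad-Tin-pMad or Tin-pMad-Tin triple. CRM activity in a tissue is the
probability mass `Σ w / Z` of configurations containing at least one
interacting *minimal unit* — pMad-Tin-pMad for the visceral mesoderm (VM),
Tin-pMad-Tin for the heart. Per-domain activity `p` maps to observables as
`expressivity = p` and `penetrance = 1 − (1 − p)^4` (four independent
scored domains). The four free parameters `(q1, q2, r_sense, r_antisense)`
are fitted by least squares on a deterministic coarse-to-fine grid with a
simplex polish.

## Worked example

```python
import crmgrammar as cg
from crmgrammar.simulate import heterotypic_design_set, simulate_scores, SimulationConfig

# 12-design pMad-Tin family; tables sampled at 100 embryos/line
designs = heterotypic_design_set()
table, truth = simulate_scores(SimulationConfig(seed=0))
params, residual = cg.fit_parameters(table, designs, cg.VM_RULE, "higher_order")
print(f"r_sense={params.r_sense:.2f} bp  r_antisense={params.r_antisense:.2f} bp  "
      f"residual={residual:.4f}")
```

prints

```
r_sense=2.58 bp  r_antisense=3.85 bp  residual=0.0004
```

i.e. the fitted interaction length scales recover the generating values
(2.5 bp and 3.9 bp) to within ~0.1 bp: sense-oriented Tin sites stop
cooperating beyond ~5 bp gaps while antisense sites reach ~7–8 bp —
the distance- and orientation-dependence that makes a 2 bp spacing change
flip a CRM's activity in one tissue but not another. The residual is the
summed squared misfit of penetrance and expressivity over the 12 designs.

A single-embryo expressivity call, the unit of the quantification module:

```python
from crmgrammar.quantify import EmbryoScore, expressivity
expressivity([EmbryoScore("e1", "VM", True, (True, True, False, False))])
# 0.5  — active in two of the four midgut VM domains
```

The same pipeline is scriptable from the shell:

```bash
crmgrammar simulate --seed 0 --out meas.tsv
crmgrammar fit --measurements meas.tsv --tissue VM --out-prefix fit
crmgrammar crossval --measurements meas.tsv --out cv.tsv
```

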