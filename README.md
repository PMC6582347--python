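# hexorient

Hexasomes are subnucleosomal particles that retain the histone H3–H4 tetramer
and a single H2A–H2B heterodimer, leaving 30–40 bp of DNA unwrapped on the
dimer-distal side. Which side of the dyad the remaining dimer occupies — the
hexasome's *orientation* — decides which flank of a gene's +1/+2/+3
nucleosomal positions becomes accessible to transcription factors.
`hexorient` is a toolkit for the computational side of that question, built
for chromatin biologists working with ChIP-exo-style histone maps and
fluorescence accessibility assays:

- **Orientation calling.** Classify each nucleosomal particle from its H2B
  (heterodimer reporter) and H4 (tetramer control) tag totals summed over 74
  bp on either side of the dyad: H2B at least 2-fold asymmetric with H4
  within 1.3-fold symmetric ⇒ an oriented hexasome; both symmetric ⇒ a
  nucleosome; H4-asymmetric particles are excluded (or kept in relaxed mode).
- **Positional sequence statistics.** Nucleotide and dinucleotide
  distributions around oriented dyads in gene orientation, up/down
  frequency-ratio profiles, block t-tests against a ratio of 1 (14 groups of
  10 positions, Bonferroni corrected), and chi-squared association tests of
  orientation against gene position, neighbouring particles and expression
  group.
- **Motif asymmetry.** PWM scanning with *exact* null p-values (dynamic
  programming over the background word distribution), upstream/downstream
  occurrence counting about the dyad, an exact two-sided binomial test of the
  split, and weak/strong H2A–H2B binding-motif classification from the side
  of enrichment.
- **Sequence design.** Widom-601 chimera construction by reverse-complement
  region interchange (e.g. −45..−23 with 23..45) and orientation-biasing
  23-bp replacements sampled from positional frequencies and filtered by
  motif score (p < 10⁻⁵).
- **ExoIII footprints.** A deterministic footprint model: nucleosomes protect
  [−72, +72], hexasomes lose 40 bp on the dimer-distal side (stall at ±32),
  with per-strand stall and fragment-length prediction and mixed-population
  stall ladders.
- **Accessibility fits.** The (ratio)_A FRET efficiency, normalized PIFE, the
  non-cooperative binding isotherm E([TF]) = E_F + (E₀ − E_F)/(1 + [TF]/S½),
  two-state Gaussian-HMM segmentation of smFRET traces, censored dwell-time
  tabulation, cumulative-exponential rate fits, and k_on/k_off extraction
  from their concentration dependence.
- **Synthetic data.** Seeded generators for every input (tag-count cohorts
  with planted orientations, composition-biased windows with planted motifs,
  titrations, telegraph-process smFRET traces) so the whole pipeline is
  testable without external downloads — and it ingests real tables (FASTA
  genome, TSV particle/expression tables, MEME minimal motifs) when you have
  them.

## Worked example

```python
import numpy as np
from hexorient import footprint, fit_isotherm, call_all
from hexorient.synthetic_data import gen_titration, gen_cohort, CohortSpec

concs = np.array([0, 2, 5, 10, 20, 35, 50, 75, 100, 200, 500, 1000], dtype=float)
hexasome = fit_isotherm(gen_titration(1.0, 0.0, 47.0, concs))
nucleosome = fit_isotherm(gen_titration(1.0, 0.0, 19.6, concs))
print(hexasome.summary())
print(f"accessibility reduction: {hexasome.S_half / nucleosome.S_half:.2g}-fold")

fp = footprint("hexasome", "left")
print(f"hexasome (dimer left) protects {fp.interval} around the dyad")

cohort = gen_cohort(CohortSpec(n_genes=200, depth=500, asymmetry_factor=3, seed=1))
calls, summary = call_all(cohort.particles)
print(summary)
```

prints

```
Non-cooperative binding isotherm fit
  E0     = 1 +/- 1.1e-09
  EF     = 6.796e-10 +/- 1.4e-09
  S_1/2  = 47 +/- 2.9e-07 nM
  ||residual|| = 5.29e-09
accessibility reduction: 2.4-fold
hexasome (dimer left) protects (-72, 32) around the dyad
label       HEX_UP  HEX_DOWN  NUCLEOSOME  AMBIGUOUS  EXCLUDED_H4
gene_index                                                      
1               55        73          72          0            0
2               61        69          70          0            0
3               66        53          81          0            0
```

The isotherm fit recovers S½ = 47 nM from the generated hexasome titration;
dividing by the nucleosome S½ of 19.6 nM gives the 2.4-fold reduction in
Gal4 accessibility on the dimer-proximal side. The footprint interval says
ExoIII digesting the top strand of a dimer-left hexasome stalls 32 bp
downstream of the dyad instead of 72. The call summary recovers the planted
orientation mix of the synthetic cohort (600 particles, Poisson depth 500,
3-fold planted H2B asymmetry).

## Layout

```
src/hexorient/
  io_formats.py        # FASTA / particle TSV / expression TSV / MEME motifs
  hexasome_caller.py   # fold-change orientation classification
  position_stats.py    # positional distributions, ratio tests, chi-squared
  motif_analysis.py    # exact-p PWM scanning, binomial asymmetry, weak/strong
  sequence_designer.py # 601 chimeras and biasing-sequence design
  footprint_model.py   # ExoIII stall / protected-interval model
  biophys_fits.py      # (ratio)_A, PIFE, isotherms, HMM segmentation, rates
  synthetic_data.py    # seeded generators for every input
  cli.py               # thin click CLI
```

See `docs/methods.md` for the models, conventions and their assumptions.
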