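# horizonte

Tools for detecting and dating **horizontal transfer (HT) of transposable
elements (TEs)** between host genomes — the analysis behind findings such
as the AviRTE retrotransposon, a LINE family shared exclusively by seven
tropical bird lineages and the filarial nematodes that cause lymphatic
filariasis and loiasis.

A TE that jumped between genomes leaves four converging signals, and this
package implements the full chain that extracts them:

1. **Unusually similar consensus sequences** in distant hosts.  Copies of
   the element are aligned and collapsed into a majority-rule consensus
   approximating the ancestral active element; consensus pairs are
   compared with the Kimura 2-parameter (K2P) distance
   (*d* = −½ ln(1−2*P*−*Q*) − ¼ ln(1−2*Q*), with *P*/*Q* the
   transition/transversion proportions, pairwise deletion of gaps).
2. **Divergence landscapes and invasion dates.**  Each copy's K2P
   distance to its consensus (CpG sites excluded) is a relative clock of
   when it inserted; the bp-weighted distribution of these divergences is
   the landscape of the element's activity.  The central 95% interval of
   the distribution gives conservative activity boundaries, converted to
   absolute ages by *t* = *d* / (2µ) with a lineage-specific neutral
   substitution rate µ (per-generation rates are scaled by a 365.25-day
   year and the host's generation time).  A two-sample *t*-test on the
   dated invasion minima asks whether transfers came in distinct bursts.
3. **Tree incongruence.**  The minimum number of host switches needed to
   reconcile the TE phylogeny with the host species tree, by exact
   transfer-only event parsimony (cospeciation, within-genome
   duplication and loss free; each host switch costs 1), with exact
   counting and enumeration of co-optimal mappings.
4. **Paleobiogeography.**  Dispersal–vicariance (DIVA) ancestral-area
   parsimony over the tropical avifaunal regions, capped at two areas
   per ancestral node, with exact per-node frequencies of co-optimal
   area sets.

Because the genome-scale inputs are enormous, a **synthetic TE-evolution
simulator** (master-gene amplification with neutral post-insertion
divergence, planted host switches, planted area histories) generates
inputs with known ground truth, so every stage is testable end to end.

## Worked example

Simulate an amplification whose activity window ran 20 → 15 Myr ago at
µ = 2.5×10⁻⁹ substitutions/site/year, then date it back from the copies
alone:

```python
import horizonte as hz
from horizonte.simulate import AmplificationParams, simulate_amplification
from horizonte.landscape import RateSpec

params = AmplificationParams(n_copies=500, window_start=20.0,
                             window_end=15.0, rate=RateSpec(2.5e-9),
                             seed=2)
master, copies, truth = simulate_amplification(params)

divs = hz.alignment_divergences(copies, truth.master_final,
                                cpg_mode="exclude")
land = hz.build_landscape(divs, taxon="simulated_host")
est = hz.estimate_activity(land, params.rate)
print(f"genome invasion:  >{est.invasion_min:.1f} Myr ago")
print(f"extinction:       >{est.extinction_min:.1f} Myr ago")
print(f"mean activity:     {est.mean_activity:.1f} Myr ago")

res = hz.wave_test([25.0, 24.3, 23.6], [20.2, 19.4, 18.6, 17.7])
print(f"two waves: t = {res.statistic:.2f}, P = {res.pvalue:.4f}")
```

prints

```
genome invasion:  >21.3 Myr ago
extinction:       >12.9 Myr ago
mean activity:     16.7 Myr ago
two waves: t = 7.93, P = 0.0005
```

The dated invasion minimum (>21.3 Myr) recovers the planted invasion at
20 Myr; the extinction minimum is conservative by construction (it is
the *earliest* point at which activity could have ceased).  The *t*-test
illustrates the burst comparison on two groups of invasion dates — here
clearly two distinct waves.

The same stages are available as subcommands of the `horizonte` CLI
(`consensus`, `distances`, `landscape`, `date`, `waves`, `reconcile`,
`areas`, `simulate`), and `horizonte pipeline --config run.yaml` executes
a whole configured run, writing a manifest with SHA-256 checksums of
every output so that runs are reproducible byte for byte.

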