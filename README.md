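# owlpellets

Small-mammal community analysis from barn-owl pellet prey remains.

Owl pellets — regurgitated masses of indigestible bone and fur deposited at
roosts — are a low-cost, non-invasive window onto the surrounding small
vertebrate community: the relative abundance of prey individuals in a pellet
series tracks their abundance in the landscape. This package implements the
statistical pipeline used to monitor threatened species (such as the Julia
Creek dunnart, *Sminthopsis douglasi*) through a native long-haired rat
(*Rattus villosissimus*) plague in semi-arid Queensland, from raw skeletal
element counts to publishable summary statistics. It is aimed at ecologists
running pellet-based monitoring programs and at anyone needing its component
estimators for abundance-count data.

## What it computes

**MNI abundance tables.** Within each pellet, the minimum number of
individuals of a taxon/age class is

> MNI = max(left mandibles, right mandibles, skulls)

— two left and one right mandible imply two individuals, and skull counts
corroborate or exceed the mandible maximum. Collection-level tables give
individuals and pellet occurrence per taxon, with percentages; pellets
yielding only unidentifiable postcranial material are tallied as one
individual each.

**Community comparison.** Each taxon's share of individuals is compared
between collection pairs via a 2×2 focal-vs-rest table with the
Yates-corrected chi-squared statistic

> χ² = N·(|ad − bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d)),

falling back to the two-sided Fisher exact test when any expected cell count
is below 5, with Holm–Bonferroni adjustment within each taxon's family of
pairwise p-values.

**Hill-number diversity.** Observed and asymptotic effective species numbers
of order q ∈ {0, 1, 2}: Chao1 richness (S_obs + ((n−1)/n)·f1²/2f2), the
exponential of the Chao–Jost entropy estimator for Hill–Shannon, and the
minimum-variance unbiased inverse Simpson n(n−1)/Σxᵢ(xᵢ−1) for Hill–Simpson,
with multinomial-bootstrap confidence intervals.

**Detection effort.** If C of N assessed pellets contain a species, the
cumulative probability of detection from n pellets is pₙ = 1 − (1 − C/N)ⁿ;
the package reports the smallest n with pₙ > 0.95 (confident detection at
α = 0.05) per site.

**Synthetic collections.** A generator with known ground truth emulates the
sampling process — multinomial prey composition shifting across a rodent
irruption, zero-truncated-Poisson item counts per pellet, unidentifiable-only
pellets, juvenile/adult splits and per-element recovery loss — so the whole
pipeline is testable against truth.

## Worked example

Bundled fixtures encode the per-taxon counts of the three present-day Toorak
collections (Initial/Winter/Summer, 2023–2024; 439, 427 and 201 individuals
from 280, 269 and 157 pellets) and the partially reconstructible Historic
collection (1994–2001). Running `python examples/03_mammal_diversity.py`
prints:

```
Initial: mammal counts {'Sminthopsis douglasi': 135, 'Sminthopsis macroura': 16,
                        'Planigale spp.': 46, 'Rattus villosissimus': 106,
                        'Leggadina forresti': 2}
  q=0: observed 5.00, asymptotic 5.00 [4.28, 5.72]
  q=1: observed 3.32, asymptotic 3.35 [3.10, 3.59]
  q=2: observed 2.92, asymptotic 2.94 [2.70, 3.19]
...
Summer:
  q=1: observed 2.51, asymptotic 2.54 [2.18, 2.90]
  q=2: observed 1.85, asymptotic 1.86 [1.59, 2.13]
```

All three collections hold five mammal species (q = 0), but the rat plague
collapses Summer to fewer than two effective dominant species (q = 2: 1.86
versus 2.94 in the Initial collection) — richness alone misses the community
shift that the abundance-sensitive orders expose. The other examples cover
the MNI summary table (`01`), pairwise comparisons (`02`, e.g. the dunnart
share dropping from 30.75% of Initial individuals to ~16% in Winter,
χ² = 25.69), detection effort (`04`, 25 pellets for confident detection of
*Planigale* spp. in the Initial collection) and a simulated boom–bust cycle
with exact truth recovery (`05`).

A thin CLI mirrors the library (`owlpellets simulate | summarize | compare |
diversity | detect | run-all`); `run-all --config cfg.yml` executes the full
pipeline and writes a hashed manifest for reproducibility.

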