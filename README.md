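# finseq

Developmental-sequence and modularity analysis of median fin
skeletogenesis, built for evolutionary developmental biologists working
on the dorsal and anal fins of bony fishes — living species surveyed as
cleared-and-stained growth series, and fossil species whose fin rays
preserve their own developmental record.

## The analysis

A growth series is coded as binary attainment states: for every
specimen, serial skeletal element (proximal radial PR, distal radial DR,
lepidotrichium L, numbered anterior→posterior) and skeletogenic event
(apparition, chondrification, segmentation, ossification, bifurcation),
state 1 if the element has reached that state, 0 if not, missing if
unobservable.  From these the package computes:

1. **SL₅₀ per element** — logistic regression of state on standard
   length SL: P(state = 1 | SL) = 1/(1 + e^−(β₀+β₁·SL)), with
   SL₅₀ = −β₀/β₁ the size at which half the specimens have attained the
   state.  Model significance is a likelihood-ratio test G = 2(ℓ₁ − ℓ₀)
   against χ²(1), gated at the Bonferroni level α/k for k elements
   tested.  Elements present in every specimen (always present), in
   none (never reached), or with perfectly ordered states (separation;
   SL₅₀ set to the bracketing midpoint and flagged) are handled
   explicitly.
2. **Rank sequences, initiation sites, direction** — elements ranked by
   ascending SL₅₀ (average ties); the initiation site is the contiguous
   run of smallest SL₅₀ (or the always-present elements); direction is
   bidirectional / antero-posterior / postero-anterior from the Spearman
   trend of SL₅₀ with distance from the site on each flank (ρ ≥ 0.5 by
   default).
3. **Modularity tests** — Spearman rank correlation r_s between paired
   sequences: dorsal vs anal fin (DAFPM, positional pairing) and
   endoskeleton vs exoskeleton within a fin (EEM, radial i paired with
   lepidotrichium i+2 per the published column layout).  A pair is
   retained only when both members are rankable; ranks are recomputed
   within the retained subset.  p-values by exact permutation (n ≤ 7)
   or the t approximation t = r_s·√((n−2)/(1−r_s²)).
4. **Fossil mode** — per-ray segment counts and first-bifurcation
   positions stand in for the unobservable ontogeny: the longest rays
   mark the initiation site of segmentation, the most proximal first
   bifurcations the site of branching, with the same direction
   classifier.
5. **Synthetic ontogenies** — a latent-threshold generator producing
   coding tables (and fossil profiles) with known truth, for validation
   and parameter-recovery studies.

The package ships the published trout (*Oncorhynchus mykiss*) SL₅₀
table for both fins and nine events as a fixture, plus schematic
reconstructions of six Palaeozoic taxa.

## Worked example

```sh
python examples/03_modularity.py
```

recomputes the modularity tests from the packaged trout SL₅₀ table and
prints, among others:

```
Dorsal and anal fin patterning module (one row per event):
   3 proximal_radial_chondrification    n=13 rho=+0.9185589  <0.001
   8 lepidotrichium_ossification        n=15 rho=+0.9576292  <0.001
   9 lepidotrichium_bifurcation         n= 8 rho=-0.4047619  ns
  10 proximal_radial_ossification       n=10 rho=+0.9268293  <0.001

Endoskeleton and exoskeleton module (within each fin):
  dorsal distal radial vs ray apparition    n=14 rho=+0.9715892  <0.001
```

Each row is one event: `n` paired elements survived the significance
filter on both sides, `rho` is the Spearman correlation of their
developmental ranks, and the stars categorize the p-value.  Strong
positive rho across nearly all events is the quantitative signature of
the two modules — the fins (and the two skeletons within a fin) build
their serial elements in congruent orders; ray bifurcation (event 9) is
the one event where the fins decouple.  Other example scripts cover
SL₅₀ estimation from simulated data (`01`), sequences/direction calls
(`02`), and fossil fins (`04`).

A thin CLI wraps the same library:

```sh
finseq reproduce-correlations          # recompute the correlation table, pass/fail per row
finseq direction --fixture --fin dorsal --event 8
finseq simulate --out sim.csv --seed 1 && finseq fit sim.csv --fin dorsal --event 4
```

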