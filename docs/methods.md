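# Methods

This note documents the models and procedures implemented in `moltnet`, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not show about real data.

## Draft reconstruction

A unigene–KO table and a KEGG-style reference database are the inputs. The
draft network is the union over all annotated KOs of the reactions they map
to; unigenes with no matched reaction are dropped. The reference flat files
follow a fixed dialect (one record per line, `": "` separators, `<=>`
equations) so that fixtures parse deterministically and round-trip exactly;
real KEGG exports would need a thin conversion step. Reaction directions come
from the per-pathway main-equation file: a reaction listed with conflicting
directions in different pathways, or with a `<=>` entry, is reversible;
a reaction absent from that file defaults to reversible with its whole
equation as main equation. A backward-only direction is normalised at draft
time by negating the stored coefficients, so "forward" always means
left-to-right as stored.

## Refinement

**Chirality.** A rule table maps variant compound ids to one canonical form;
the shipped default is the glucose class (unspecified and β-D-glucose to
α-D-glucose, the predominant cellular anomer). The table is configuration:
genome-wide chirality curation is out of scope. A reaction whose sides
collapse onto the canonical id is flagged degenerate and retained (it drops
out of the topology layer naturally because its main equation empties).

**Pathway assignment.** Each reaction gets exactly one pathway: the smallest
numeric map id among its annotations that has a subsystem entry, excluding
global/overview maps (011xx). One pathway per reaction is what makes
pathway-scale gap filling well defined.

**GPR rules.** Unigenes reach enzymes through shared KOs. All unigenes
matching one enzyme form an AND group (they are treated as subunits — a
deliberate simplification that can overstate complexes when isoforms share an
enzyme); different enzymes of a reaction are ORed. KOs not covered by any EC
number act as singleton enzyme units so annotation without EC linkage still
yields a rule. A reaction may legitimately have no GPR (boundary, gap and
evaluation reactions).

**Confidence.** 0–4 by evidence class: sequence-evidenced draft reactions
and physiologically motivated additions (boundary, biomass, evaluation)
score 2; connectivity-only gap reactions score 1.

## Biomass

The water entry fixes dry weight (100 − water g per 100 g wet). Every other
entry converts as `content / molar_mass × 1000 / dry_weight` mmol/gDW, with
mg/kg entries first scaled by 10⁻⁴ to g/100g. Precursors are consumed;
ATP maintenance is embedded as ATP + H₂O → ADP + Pi at 29.8303 mmol/gDW
(a hamster-cell-model value adopted as the default; tunable). Trace elements
enter as free ions. For a mass-closed composition the precursor coefficients
reproduce 1000 mg per gDW exactly, which the tests assert to 1%.

## Gap filling

Two reactions are adjacent when they share a non-currency main-equation
metabolite; the biomass pseudo-reaction is excluded. Currency carriers are
excluded from adjacency because they would glue the whole network into one
component and hide every real breakpoint. The environment is the reference
database minus the reconstruction. Pathway scale first: per pathway (sorted),
candidates annotated to that pathway that merge ≥ 2 of its WCCs are added
greedily. Global scale second: while any candidate merges ≥ 2 global WCCs,
the best one is added and the partition recomputed. Ranking: most components
merged, then pathway affinity (candidate's pathway present in ≥ 2 touched
components > in one > same subsystem > none), then lexicographic id. The
search is greedy and non-backtracking — it mirrors component-merging rather
than parsimony optimisation, so no LP/MILP gap filler is involved. "Similar
pathway" is operationalised as the subsystem tie-break; that is this
package's choice where the procedure is under-specified. Dead-end metabolite
counts are reported before/after but are not the objective.

## Constraint-based model and evaluation

The model is a COBRA model (GLPK solver, deterministic) with S·v = 0 and the
bounds policy tabulated in the README; negative exchange flux is uptake.
Exchange reactions are classified from the composition's nutrient classes
plus fixed id sets (the ten non-essential amino acids; freely exchanged
H₂O/H⁺/O₂); an unclassifiable exchange is an error, never a silent default.
Synthesizable fatty acids are detected operationally: close every fatty-acid
exchange, then test each acid's maximum production; producible acids get
(0, 1000), the rest remain nutrients at (−5, 1000).

Evaluation maximizes, in turn, each non-essential amino acid's exchange, the
biomass reaction, and ecdysone secretion with cholesterol uptake opened at
(−5, 1000). A zero flux triggers one-step backtracking: substrates of the
target's producing reactions with no other producer and no exchange are
reported; for amino acids the pipeline opens uptake for them (the sulfide
case of the cysteine route), for biomass precursors the report lists
candidate producing reactions from the environment ranked by pathway
affinity. Only objective values are contract-bearing; alternate optimal flux
vectors are resolved arbitrarily by the solver, and reported vectors are
verified against |S·v| < 10⁻⁶. Biomass flux is in g dry weight per hour
(one flux unit produces one gram). SBML Level 3 (fbc) export/import
preserves S, bounds, objective and gene associations.

## Topology

Currency metabolites (default: ATP, ADP, NAD⁺/NADH, NADP⁺/NADPH, water,
protons, phosphate, O₂, CO₂ — configurable) are deleted from main equations;
exchange and biomass reactions are dropped, as are reactions whose main
equation empties. In the reaction graph, r₁ → r₂ is an arc when a main
product of r₁ (in an allowed direction) is a main substrate of r₂; a
symmetric connection becomes a single undirected edge, so a node pair carries
either one edge or up to two arcs, never both. Average degree counts all
incident arcs and edges (Pajek-style); density, path length, diameter and
clustering are computed on the direction-collapsed simple graph, path
metrics on its biggest component. The bow-tie of the biggest WCC takes the
largest strongly connected component (ties by smallest member id) as GSC,
its ancestors as S, its descendants as P, and the remainder as IS. The
random ensemble compares observed clustering with `gnm` random graphs of
equal node and link counts (default 100 replicates, seeded).

## Module decomposition

Average-linkage agglomerative clustering on all-pairs shortest-path
distances of the collapsed biggest WCC gives the classification tree (the
method is pluggable; this default is deterministic and parameter-free). The
tree is traversed top-down until every subtree is at most `max_size` leaves;
modules under `min_size` merge into the largest linked module (smallest
offender first; an unconnected module stays); greedy single-node moves
between linked modules then refine the partition, accepting a move only when
ΔQ > 10⁻¹² under a deterministic sweep order, so Q never decreases; a final
merge pass restores the size floor if refinement shrank a module. Q is
Newman modularity on the collapsed simple graph. Defaults are max 50 /
min 10, the scale used for thousand-reaction organ networks; the pipeline
runs the ~100-node synthetic component at max 20 / min 5, keeping the same
proportion to network size. The module count itself is a property of the
input network and the clustering method, not a contract.

## Differential expression

Clean-read rules: drop adaptor reads, reads with > 10% unknown bases, and
reads where > 50% of bases have Phred quality ≤ 5 (Phred+33; both rules are
strict inequalities). Expression is RPKM = 10⁹·count/(total·length).
Significance for a replicate-free library pair is the exact conditional
binomial test of the count pair given library totals (the standard
single-replicate digital-expression test; pluggable), two-sided, BH-adjusted.
Flags require FDR ≤ 0.001 and |log₂ ratio(C1/C0)| > 1 on RPKM; a zero count
on one side gives an infinite ratio, which passes the ratio criterion by
convention, and no pseudocount is added for the test. A reaction is
differential when any GPR leaf is a differential unigene; per-module rollups
count differential unigenes by direction.

## Synthetic data: what it emulates and what it does not

`make_refdb` builds a deterministic ~60-reaction world: a glycolysis-like
backbone with ATP/NAD(H) cofactors, oxidative phosphorylation and an ATPase
written as currency-only reactions (they exercise the all-currency pruning
rule), the ten non-essential amino acids including a sulfide-dependent
cysteine synthesis whose sulfur source is deliberately absent (the
evaluation repair case), an elongating fatty-acid chain, a five-step
cholesterol→ecdysone route with no other connection to the network, a small
nucleotide branch, and the three glucose anomers. Phosphorus is conserved in
every reaction, with phosphate entering as a mineral nutrient — without that
the biomass objective would be infeasible for bookkeeping rather than
biological reasons.

`make_annotations` holds out gap reactions chosen among articulation
reactions of the reference adjacency graph, validated jointly (each one,
re-added alone, reconnects ≥ 2 components) and under the same conventions
the analysis applies (currency excluded, glucose canonicalized); with full
coverage the environment then contains exactly the held-out bridges, so
exact recovery is a property of the construction. `make_counts` draws
lognormal baseline expression (σ = 0.5 on the log scale, mean count
totals/n = 200 at defaults) and plants 10-fold changes in 5% of unigenes;
`make_composition` mirrors whole-cell assay class totals (protein 7.81,
lipid 33.7, water 54.2, carbohydrate 1.05, trace 0.74 g/100 g; nucleotides
at mg/kg level) with seed-jittered within-class shares rescaled to close
mass exactly. A single seed fans out to per-stage seeds via
`child = (seed·1000003 + stage) mod (2³¹−1)`.

Passing tests on these fixtures show the algorithms are implemented
correctly, deterministic, and faithful to their stated rules. They do not
show that a real organ reconstruction would reach any particular size or
flux: real KEGG releases are orders of magnitude larger, annotations are
noisy and incomplete in ways the coverage parameter only caricatures, real
libraries have overdispersion beyond Poisson, and real gap filling faces
many interchangeable candidates rather than planted unique bridges.

## Known limitations

- The flat-file dialect is fixed; real KEGG exports need conversion.
- Gap filling is greedy component merging; it does not guarantee minimal
  additions nor thermodynamic plausibility of added reactions.
- The AND rule over same-enzyme unigenes can inflate complexes when
  isoforms or fragments share an enzyme annotation.
- No flux variability analysis, gene deletions, or loopless FBA.
- The exact test assumes Poisson sampling; with biological replicates a
  dispersion-aware model should replace it.
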