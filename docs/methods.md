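# Methods

This note records the models, conventions and numerical choices behind
`circuitsym`, and what the synthetic fixtures do and do not establish
about real connectome data.

## Circuits and the commutator norm

A circuit is a labeled nonnegative-integer matrix `A` with zero diagonal;
gap-junction circuits are symmetric (each undirected link stored in both
orientations), chemical circuits directed. The total weight `M` counts
each undirected link once and each directed link once.

For a permutation `P`, `P A P⁻¹` is a rearrangement of the entries of
`A`, so the raw L1 sum `Σ_ij |A_ij − A_{P(i)P(j)}|` counts every *moved*
link unit twice — once where it disappears and once where it reappears —
and, for symmetric matrices, in both orientations. We therefore define

```
‖[P, A]‖ = Σ_ij |A_ij − A_{P(i)P(j)}|  / (2 if directed else 4)
```

so that the norm is *the number of link units the permutation fails to
preserve*: a permutation that relocates exactly one unit-weight link
scores 1. This calibration makes the canonical worked example come out
right — a transposition that breaks one link in a circuit of 18 weighted
links has ε = ‖[P,A]‖/M = 1/18 ≈ 5.6% — and keeps the norm integer-valued
for integer weights. ε is dimensionless; permutations with ε < 0.25 (the
reported animal-to-animal wiring variability) are flagged biologically
plausible. A config switch (`denominator="support"`) restricts `M` to
links incident to the permutation's support for a stricter local reading.

## Exact symmetry enumeration

`automorphism_group` backtracks over a weighted 1-WL color refinement:
initial colors are refined by multisets of (weight, neighbor-color) pairs
(in- and out- separately for directed circuits) until stable; the search
assigns images only within color classes, pruning on weight consistency
with all previously assigned nodes. Guards: `n ≤ 64` nodes and a group
order cap of 10⁶ (both configurable); beyond them the caller is directed
to sector-wise analysis. For `n ≤ 7` the test suite checks the result
against exhaustive `n!` filtering.

## Pseudosymmetry search

The full permutation space is never enumerated for approximate symmetry.
The deterministic three-stage search: (1) exact automorphisms; (2) every
transposition with ε ≤ ε_max; (3) candidate sectors = connected components
of the graph on nodes whose pairwise swap costs are ≤ ε_max, each tested
against subgroup templates — the full symmetric group (generators: all
within-sector transpositions), cyclic rotations (sectors of size ≤ 6, all
orderings), and a single pair-matching involution (greedy matching by
ascending swap cost). A template's ε is the **maximum** generator ε
(conservative); the mean is logged alongside. Output order is fully
deterministic: ε ascending, support size descending, lexicographic.

Pseudosymmetries do not form a group (composing two may break more than
ε·M links); the pipeline therefore takes the closure of the accepted
template generators together with the exact group, with a 10⁶-element
cap. If an over-permissive ε_max makes that closure explode, the pipeline
falls back to the exact group and keeps the candidates on record. Note a
practical consequence of integer weights: in a lightly weighted circuit
one link unit may already be a sizable fraction of `M` (0.8% in the
21-node ideal fixture), so distinguishing planted sectors requires
ε_max below that granularity; real circuits, with larger and more
heterogeneous weights, separate at looser tolerances.

## Group algebra and factorization

Groups are materialized element sets (image tuples) with BFS closure;
generating sets are reduced greedily. Normality uses conjugation by a
generating set only (conjugation by a product composes). Factorization
starts from the orbit partition and merges orbit groups whenever a
generator's restriction to a candidate component (identity elsewhere) is
not a group member — restriction to a fixed component is a homomorphism,
so testing generators suffices. Each final component gives a factor
(the set of restrictions); verification (factor orders multiply to |G|,
mutual normality) failures set a `residual` flag rather than raising.
Fixed points of the whole group belong to no sector.

Naming: order-2 groups are `C_2` when the involution is a single 2-cycle
and `D_1` when it moves more than two points; cyclic groups `C_n`;
dihedral groups are named by their order (`D_8` = the square's 8-element
group) with a switch for polygon-style naming; full symmetric action on
the k moved points is `S_k`; anything else reports `other(order)`.

## Blocks of imprimitivity

For a factor transitive on its sector, minimal block systems come from
the classic seed-pair union-find refinement (merge the seed pair,
propagate generator images until stable), deduplicated over all seeds;
trivial systems are excluded from the nontrivial listing. Intransitive
factors — typically a lone involution pairing nodes across two conjugate
blocks — cannot be handled by that algorithm (its refinement never leaves
an orbit), yet sets spanning several orbits can still satisfy the block
property. `sector_block_candidates` enumerates the valid conjugate splits
of the sector: the orbit partition, connected components of each
edge-weight class of the sector's induced subgraph, and (for pure
involutions on ≤ 6 orbit pairs) all transversal splits `{B, σ(B)}`. Every
candidate is verified against the block property for every group element;
structurally connected systems are ranked first, since they are the ones
realizing internal circulant cycles.

## Circulant structure

Exact detection fixes the first label and tries all orderings for blocks
of size ≤ 8; larger blocks search the block's automorphism group for a
regular ℓ-cycle (flagged heuristic). The nearest pseudocirculant
minimizes the fraction of differing link units — per candidate ordering,
the best constant per cyclic diagonal is an integer median — with
deviation = L1 difference / max(weight of matrix, weight of fit), ties
broken to the lexicographically smallest first row then ordering
(exhaustive for ℓ ≤ 10). Eigen-analysis uses the DFT of the first row;
palindromic (symmetric) rows get a real orthonormal cosine/sine basis
with degenerate pairs, signs fixed by first-nonzero-positive. The filter
catalogue is exact-match: `circ(0,1)` → H, `circ(1,1)` → L,
`circ(0,1,0,1)` → F, all-zero → zero, else `other` with the DFT magnitude
attached as frequency response.

## Idealization

The ε → 0 circuit is the group average of `A`: every orbit of ordered
node pairs under the group receives the rounded mean of its weights,
rounding performed orbit-wise with halves up. Orbit-constant values make
every group element an exact automorphism of the result by construction,
the operation idempotent, and the rounded mean the L1-minimizing
orbit-constant integer. Pair orbits are computed by union-find over
generator images, so the cost is independent of group order.

## Null model and p-values

The null preserves the weighted degree (strength) sequence exactly:
weights are expanded into unit links and rewired by double-edge swaps
((a,b),(c,d) → (a,d),(c,b); all four endpoints distinct, self-loops
rejected, weight merging allowed), 10 attempted swaps per link unit by
default, deterministic per seed. An unweighted-degree variant swaps whole
weighted links and additionally rejects merges (a merge would change link
counts). The p-value of a subgroup of a given type and sector size is the
fraction of R null circuits containing a same-type subgroup anywhere with
ε* ≤ the observed ε; the best null subgroup uses an exhaustive
transposition scan for C₂ and greedy sector-growth / matching for S_k and
D₁ (a slight over-estimate of ε*, hence conservative for p). The guarded
estimate (1 + count)/(R + 1) is reported alongside. Desk-scale default is
R = 1000 via the library, 0 (disabled) in the CLI pipeline unless
requested; resolving p-values near 10⁻⁶ requires R ≫ 10⁶ and is left to
the flag.

## Linear filter dynamics

`τ dv/dt = −v + Mv + Wu` is integrated with fixed-step RK4 (guard
dt < τ/2); the steady state solves `(I − M)v = Wu` and raises, naming the
unit eigenvalue, when singular. For circulant `M` the Fourier modes
evolve independently at rates (λ − 1)/τ; the λ = 2 mode of the
subsampling kernel is genuinely unstable under this linear model and is
reported as such rather than saturated. τ defaults to 1 and all times are
in units of τ.

## Synthetic circuits

`plant_circuit` assembles sectors (S_k: identically hub-wired nodes with
empty internal block; C_k: a ring; D_1: two equal blocks with internal
circulant template and a symmetric cross-block coupling) around hub nodes
with per-node feedforward weights, then *verifies* that every planted
generator is an exact automorphism, raising with the offending sector
otherwise. The planted product is contained in — and for the shipped
fixtures equal to — the circuit's full symmetry group.

The 21-node ideal forward fixture reconstructs the published block
structure: command block `bcirc(H, L)` on (AVBL, AVBR | RIBL, RIBR), an
S₅ motor set wired only to the hubs, the D₁ sector as two conjugate
4-cycles `circ(0,1,0,1)` with a symmetric cross-block matching, and two
motor pairs at hub weights 6 and 7. Two reconstruction choices were open
and are this package's own: (i) the printed cross-block coupling of the
motor blocks is asymmetric, which cannot hold exactly in an undirected
circuit — the fixture uses its symmetrization (each printed link plus its
σ-image); (ii) with unit cross-block weights the 8-node sector is the
cube graph, which has an extra involution beyond σ — the cross-block
links carry weight 2 to break it, and hub weights are constant on
σ-orbits but distinct across them (3/2/1/4). With these choices the
fixture's automorphism group is exactly C₂×C₂×S₅×D₁×C₂×C₂, order 3840.

`perturb` changes `round(f·M)` link units (remove a random existing unit
or add a unit to a random pair, probability ½ each), emulating the 25%
animal-to-animal variability at the same granularity as the norm.

**What the fixtures do not show:** they are idealized, lightly weighted
and 21 nodes; passing on them demonstrates the algebra and the search
logic, not robustness to the weight heterogeneity, measurement error or
missing links of real reconstructions. Analysis of a real connectome
requires the user to convert the public wiring tables to the documented
TSV; no scraped data ships with the package.

## Baselines

Louvain modularity (best of 8 seeded restarts) and power-iteration
eigenvector centrality, both on the weighted graph via networkx, are the
comparison partitions; agreement with symmetry sectors is the adjusted
Rand index (sklearn). These are reference points, not part of the
symmetry method.

## Problem sizes

Default test and acceptance runs use the in-package fixtures (≤ 21
nodes, group orders ≤ 3840, null ensembles R ≤ 200, brute-force oracles
up to 8! per sector); all are the package's own desk-scale choices and
complete in seconds.
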