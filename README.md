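# circuitsym

Symmetry-group analysis of small weighted neural circuits, built around the
locomotion circuits of *C. elegans* (command interneurons driving ventral/
dorsal motor neurons through gap junctions and chemical synapses).

The package is for researchers who ask how circuit *structure* determines
*function*: it detects the permutation symmetries of a weighted connectome,
tolerates the ~25% animal-to-animal wiring variability through approximate
("pseudo") symmetries, factorizes the symmetry group into normal subgroups
whose neuron *sectors* match functional categories, and reads the finer
block structure of each sector as a set of circulant linear filters.

## The model

A circuit is a weighted adjacency matrix `A` (entry `A_ij` = number of
connections between neurons `i` and `j`; gap junctions undirected, chemical
synapses directed). A node permutation `P` is an **automorphism** when it
commutes with the wiring,

```
[P, A] = PA − AP = 0 ,
```

and a **pseudosymmetry** at uncertainty ε when the commutator norm — the
number of link units `P` fails to preserve — is below a fraction ε of the
circuit's total link weight `M`:

```
‖[P_ε, A]‖ < ε·M ,       ε < 0.25  ⇒  biologically plausible.
```

The set of exact automorphisms forms the circuit's symmetry group **G**,
which factorizes as a direct product of normal subgroups, each acting on a
disjoint sector of neurons, e.g. for the ideal forward gap-junction circuit

```
F_gap = [C₂ × C₂] × [S₅ × D₁ × C₂ × C₂]
```

(command sector × motor sector). Inside a sector, conjugate **blocks of
imprimitivity** carry **circulant** matrices — `H = circ(0,1)` (high-pass),
`L = circ(1,1)` (low-pass), `F = circ(0,1,0,1)` (subsampling kernel, with
eigenvalues −2, 2, 0, 0 on the Fourier modes) — nested into block-circulant
arrangements such as `bcirc(H, L)`. These act as the linear filters of a
feedforward + recurrent rate model `τ dv/dt = −v + Mv + Wu`. Statistical
significance of every subgroup is assessed against degree-preserving
double-edge-swap null ensembles.

## Worked example

Analyze the shipped 21-neuron ideal forward gap-junction circuit:

```bash
circuitsym analyze src/circuitsym/data/forward_gap_ideal.tsv \
    --eps-max 0.005 --out report.json
```

The Markdown companion of the report reads:

```
# Circuit analysis (21 neurons, gap, M = 124)

| sector | eps | subgroup | p-value |
|---|---|---|---|
| (AVBL, AVBR) | 0.0% | C_2 |  |
| (RIBL, RIBR) | 0.0% | C_2 |  |
| (DB5, DB6, DB7, VB10, VB11) | 0.0% | S_5 |  |
| (DB1, DB2, DB3, VB1, VB2, VB4, VB5, VB6) | 0.0% | D_1 |  |
| (VB3, VB7) | 0.0% | C_2 |  |
| (VB8, VB9) | 0.0% | C_2 |  |

Factorization: 6 normal subgroups; group order 3840.

- D_1 blocks [DB1,VB4,VB5,VB6 | DB2,DB3,VB1,VB2] filters [F,F] block-circulant

Idealization distance: 0.0 link units (0.0% of M).
```

Reading: the symmetry group (order 3840) splits into six normal subgroups;
the two command pairs (AVB, RIB) are each exchangeable, five motor neurons
are fully interchangeable (S₅), and the eight-neuron motor sector carries a
single involution (D₁) whose two conjugate 4-blocks are internal
`circ(0,1,0,1)` cycles combined block-circulantly. All ε are 0 because the
input is the ideal circuit; on a perturbed circuit each row reports the
fraction of link units its generators break.

The uncertainty constant itself, on an 18-link circuit in which swapping
DB5 and DB6 moves exactly one link (DB5 carries one link to AVBR that DB6
lacks; `tests/conftest.py` builds this circuit):

```python
>>> from circuitsym import epsilon, Permutation
>>> ps = epsilon(c, Permutation.transposition(c.labels, "DB5", "DB6"))
>>> ps.norm, round(ps.eps, 4)
(1.0, 0.0556)          # 1 broken link / 18 = 5.6%, well inside the 25% bound
```

Synthetic circuits with planted symmetry and controlled noise come from
`circuitsym plant` / `circuitsym perturb` (YAML specs, see
`circuitsym.synthetic_data`), baselines from `circuitsym baselines`, and
the block dynamics from `circuitsym dynamics --first-row 0,1,0,1`.

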