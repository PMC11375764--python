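# allonet

Connectivity analysis of amino-acid interaction networks in homodimeric
proteins.

Point mutations in multi-domain enzymes — the motivating case is the
photoreceptor guanylate cyclase GC-E (retGC1), where a substitution in the
catalytic domain rewires allosteric control exerted from the distant
dimerization domain — can alter how structural information travels through
a protein without large structural rearrangements. `allonet` quantifies
such changes on residue interaction networks: it takes one structure
snapshot per variant (e.g. the final frame of an MD simulation), reduces
each residue to its Cα position, connects residue pairs closer than a
distance threshold (8 Å by default), and computes two complementary
per-residue connectivity measures that it then compares between a
wildtype and a mutant snapshot. It is aimed at structural bioinformaticians
who want a reproducible, testable version of this analysis that runs on
plain PDB input — or entirely on built-in synthetic structures.

## The measures

Let A be the binary adjacency matrix of the contact network over both
monomers (2N residues, monomer 1 first), with a_ij = 1 iff the Cα–Cα
distance d(i, j) is strictly below the threshold.

**Betweenness.** For each residue i,

    β(i) = Σ_{u<v, u≠i≠v} σ_uv(i) / σ_uv,

where σ_uv is the number of shortest paths between u and v and σ_uv(i)
the number of those passing through i (unnormalised; disconnected pairs
contribute 0). High-β residues sit at the intersections that shortest
routes between domains must cross.

**Reach (communicability).** Since (A^k)_ij counts walks of exactly k
steps, the matrix exponential

    G = e^A = Σ_k A^k / k!

accumulates walks of every length, down-weighting long ones by 1/k!. G is
split into four N×N blocks; the two intra-monomer blocks G¹¹ and G²² are
averaged element-wise into Ḡ (the cross blocks are diagnostics only), and
the reach of residue i is the column sum ρ(i) = Σ_j Ḡ_ji. Betweenness is
likewise reported per monomer, β₁(i) and β₂(i), and averaged.

**Variant comparison.** For a reference (wildtype) and an alternative
(mutant) profile, Δβ(i) = β_ref(i) − β_alt(i) and Δρ(i) = ρ_ref(i) −
ρ_alt(i). Positive values mean greater connectivity in the reference; the
residues at the two ends of the sorted Δ list (top 6 per end by default)
are the candidates for functionally important positions.

## Worked example

Generate a synthetic 120-residue-per-monomer dimer, a "mutant" copy of it
with a localized 2.5 Å perturbation around position 60, and compare the
two variants:

```sh
allonet simulate --n-res 120 --seed 42 --interface-contacts 20 --out wt.pdb
allonet simulate --n-res 120 --seed 42 --interface-contacts 20 \
        --perturb 60:2.5:5 --out mut.pdb
allonet network    --structure wt.pdb  --out wt.graphml
allonet centrality --structure wt.pdb  --label wt  --out wt.tsv
allonet centrality --structure mut.pdb --label mut --out mut.tsv
allonet compare    --ref wt.tsv --alt mut.tsv --top 6 --out delta.tsv
```

which prints (network step):

```
240 nodes, 970 edges (intra 477/477, inter 16); degree min/mean/max 3/8.08/17
```

— 240 nodes because both monomers enter the network, with 16 interface
contacts near the requested 20 — and (compare step):

```
beta: top (reference-greater): 16(+1383), 63(+725.2), 62(+549.4), 7(+534), 21(+465.6), 67(+328.6)
beta: bottom (alternative-greater): 86(-1208), 88(-1005), 9(-791.8), 52(-741), 119(-371.7), 117(-264.7)
rho: top (reference-greater): 16(+523.3), 11(+229.4), 21(+222.3), 10(+210.1), 14(+205.9), 18(+199.3)
rho: bottom (alternative-greater): 56(-6.8e+04), 57(-6.6e+04), 48(-6.384e+04), 42(-5.406e+04), 61(-5.327e+04), 46(-5.301e+04)
```

The strongest reach gains of the "mutant" (bottom `rho` list, negative Δρ)
cluster at positions 42–61, i.e. at and around the perturbed site — the
pipeline localises the planted connectivity change. The same analysis runs
from a single YAML config via `allonet run --config config.yaml`, which
also writes a JSON manifest from which the whole run can be reproduced
byte-for-byte (`allonet run --manifest out/manifest.json`).

Real structures work the same way: point `--structure` at a two-chain PDB
file, select chains with `--chains A,B`, and shift reported residue
numbers between orthologue numbering conventions with
`--renumber-offset` (e.g. −5 to report bovine position 907 as human 902).

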