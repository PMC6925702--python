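# Methods

## The physical model

The package treats a conductive type IV pilus as a one-dimensional molecular
wire whose charge carriers hop between aromatic residues (Phe/Tyr rings) in
the non-adiabatic Marcus regime. Its assumptions, in order of consequence:

1. **Helical symmetry.** The filament is generated from one pilin subunit by
   a screw operator (rise *h*, rotation *φ* per subunit, right-handed by
   default). All pathway geometry therefore repeats with period one subunit,
   and one "smallest symmetric unit" — four rings, F1 of subunit P−1 through
   F24 and Y27 to F1 of subunit P — characterizes the whole wire.
2. **Series bottleneck.** The per-repeat transfer rate is limited by the
   slowest step, associated with the largest of the unit's three
   interaromatic distances d₁ (F1,F24), d₂ (F24,Y27), d₃ (Y27,F1). The
   transport chain uses that lowest rate as the effective rate W₀.
3. **ΔG° = 0 upper bound.** Site energies of symmetry-equivalent aromatics
   are taken as equal, so the Marcus rate reduces to its prefactor
   w = (t²/ħ)√(π/(λk_BT)). All downstream quantities are therefore upper
   bounds; this is deliberate — the question is whether π-stacking *can*
   account for metallic-like conduction, not a prediction of the exact value.
4. **Scalar electronic structure.** Transfer integrals t (half the dimer
   HOMO/HOMO−1 or LUMO+1/LUMO splitting) and the four-point reorganization
   energy λ = (E_cn^D − E_nn^D) + (E_nc^A − E_cc^A) come from external
   quantum-chemistry calculations; the package ingests them as scalars and
   never attempts to estimate couplings from geometry.

The ladder is then D = W₀Z₀² (1-D diffusion), μ = eD/k_BT (Einstein),
ρ = n/(πr₀²z₀) (carrier density; n = 4 aromatics per unit in a cylinder of
radius r₀), σ = eρ(μ_h+μ_e), and G = σS/l.

## Parameters, units, defaults

| parameter | unit | default | rationale |
|---|---|---|---|
| temperature T | K | 298 | ambient; makes the D → μ chain internally consistent with three-significant-figure source values (300 K errs by ~0.7%) |
| reorganization λ | eV | input (0.37 typical) | same λ for every aromatic site on the pathway |
| periodic-cell height Z₀ | Å | 3.10 | derived convention: back-solved from D = W₀Z₀² so the ladder is self-consistent across both carriers and both models; not an independently measured length |
| packing radius r₀ | Å | 13 | radius of the aromatic packing cylinder |
| carriers per cell n | – | 4 | four rings per symmetric unit |
| pathway edge cutoff | Å | 7.0 | covers the largest pathway step (6.1 Å) while excluding ≥ 8.7 Å intra-subunit ring pairs |
| subunit index P | – | 7 | first subunit of the second helical turn |
| restraint (x₀, sd, tol), coarse | Å | (10, 0.5, 5) | Cα–Cα flat-harmonic band |
| restraint (x₀, sd, tol), all-atom | Å | (4, 2, 0.5) | N–O salt-bridge pairs; x₀ = 4 Å is the canonical salt-bridge N–O distance, which fixes the otherwise ambiguous ordering of the three values |
| RMSD cluster cutoff | Å | 1.75 | structural-similarity clustering of decoys |
| DBSCAN (ε, minPts) | °, – | (3, 10) | rotation-angle basin detection |
| subunit count | – | 21 | chains A…U |

Energies stay in eV and lengths in Å throughout the math; conversion to SI
(via e, ħ, k_B from `constants.py`, 2019 exact values) happens once, at the
type boundary. The carrier density may be supplied directly (`rho_per_m3`)
because the cylinder-height reading of the density formula is ambiguous
between Z₀ and the full symmetric-unit height (~18.8 Å reproduces
ρ ≈ 4×10²⁶ m⁻³ at r₀ = 13 Å); when supplied, the formula is bypassed and the
provenance recorded in the result's audit trail.

## Numerical and algorithmic choices

- **Flat harmonic.** Implemented as the standard symmetric form — zero on
  [x₀−tol, x₀+tol], ((|d−x₀|−tol)/sd)² outside — continuous at both band
  edges; penalizes both too-short and too-long contacts. Ambiguous
  restraints take the minimum penalty over candidate pairs (per-pair, not
  per-assembly).
- **Dijkstra.** In-package implementation with a contractual deterministic
  tie-break: among equal-length paths, the lexicographically smallest
  sequence of (subunit, residue) node keys wins. Edge weight is the
  centroid–centroid distance; the proximal carbon–carbon distance (min over
  the 36 ring-carbon pairs) is reported alongside but never weights edges.
- **Ring normal.** Smallest principal component of the six centered ring
  carbons, sign toward +z (ties cascade +z → +y → +x).
- **Superposition.** Kabsch via SVD (`scipy` rotation alignment), proper
  rotation guaranteed; RMSD symmetric in its arguments.
- **k-means / DBSCAN.** scikit-learn, Lloyd's algorithm with seeded
  restarts (default seed 1234, logged); angles treated as plain scalars
  since the relevant basins (≈30–165°) never straddle the 0/360 wrap
  (a circular-metric flag exists, off by default).
- **Leader clustering.** Energy-ascending greedy assignment to the first
  cluster whose founding model is within the RMSD cutoff; the published
  tool's exact algorithm is unpublished, so this documented greedy variant
  is adopted.
- **Degenerate inputs.** Empty structures, missing ring atoms, non-positive
  λ/T/sd, collinear Cα sets, subunit-size mismatches and unresolvable atom
  selectors raise typed errors naming the offending entity; a pathway unit
  that is not the canonical four rings triggers a warning carrying the
  actual membership rather than an exception.

## What the synthetic generators emulate — and what they do not

`make_ideal_pilin` emits a 61-residue poly-alanine α-helix as a Cα trace
(1.5 Å rise, 100° twist, radius set so consecutive Cα are exactly 3.8 Å
apart) with full six-carbon rings grafted at the mature aromatic positions.
`make_pathway_pilus` plants an exact (d₁, d₂, d₃) triple: the F1 anchor sits
on a 5 Å-radius cylinder, the helical operator (default 10.5 Å rise, 100.8°
rotation) fixes the F1→F1 span, and F24/Y27 are placed by a deterministic
planar three-bar-linkage construction; infeasible triples raise before any
structure is built. Off-pathway aromatics (Y32, F51, Y57) are parked on a
20 Å shell, verified ≥ 8 Å from every pathway ring so the 7 Å cutoff keeps
them off the shortest path.

These fixtures are geometrically ideal: no side-chain chemistry, no thermal
disorder (unless noise is added explicitly), no surface heterogeneity, and
rings whose centroids sit exactly at the planted distances. Tests passing on
them demonstrate the correctness of the geometry, graph and transport
machinery — not that a real pilus has these distances. Conversely, the
transport chain's agreement with externally derived diffusion coefficients
and mobilities is a statement about the formula chain and its constants, not
about the underlying quantum-chemistry inputs, which the package consumes as
given.

## Problem sizes

Default study conditions: 21-subunit assemblies (126 rings, ~7.9k candidate
ring pairs), 100-model clustering ensembles, 50 random ≤ 8-node graphs for
the path-enumeration cross-check. The whole test suite and the acceptance
script each complete in seconds on one CPU.

## Known limitations

- No docking search: helical parameters are inputs (or planted), never
  optimized; interface-energy ranking of decoys is out of scope.
- No estimation of couplings or λ from geometry; no ΔG°-dependent rate, so
  every transport number is an upper bound.
- Conductance depends on a conductor cross-section S and length l that are
  geometric conventions (ring area ≈ 30 Å², bottleneck distance); it is
  reported as order-of-magnitude, not as a precise prediction.
- PDB writing supports single-character chain ids (62 chains); larger
  assemblies exist in memory with two-character ids but cannot be exported
  to PDB.
- Multi-model (NMR) files: one model is read at a time (selectable index),
  with no ensemble averaging.
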