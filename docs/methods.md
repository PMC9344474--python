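# Methods

## The model

`watblocks` treats DNA hydration as a local, transferable property of
dinucleotide steps. The working assumptions are:

- The first hydration shell around a dinucleotide depends on its
  conformer class (NtC) and 2-letter sequence, and only weakly on the
  wider structural context; pooling waters across many structures of
  the same combination therefore averages out crystal-specific noise
  while reinforcing conserved sites.
- Water positions can be carried between copies of a step by a rigid
  transform fitted to the step atoms nearest the water. Using the six
  nearest atoms rather than the whole step makes the transfer robust to
  internal flexibility: the local frame around the water is what
  determines its position, not the far end of the fragment.
- Preferred water positions are maxima of the pooled probability
  density, and the biologically meaningful quantity is the *occupancy*:
  waters within 1 Å of the site divided by the number of contributing
  steps, i.e. the probability that a given step carries a water there.

Hydration of a whole structure is then the superposition of its steps'
hydrated blocks. Because overlapping steps share atoms, their water
clouds are accumulated into one pair of global grids (base and
backbone), so sites supported by adjacent steps reinforce.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d_assoc` | 4.0 Å | water-to-step association cutoff |
| `d_calc` | 3.4 Å | base/backbone category cutoff; also the water-counting cutoff in curation |
| `r_occ` | 1.0 Å | occupancy-counting radius around a site (boundary inclusive) |
| `min_waters_reliable` | 800 | accumulated waters needed for a combination to count as reliable |
| `transfer_rmsd_max` | 0.75 Å | six-atom superposition r.m.s.d. above which a water transfer is rejected |
| `spacing` | 0.2 Å | density-grid voxel edge |
| `sigma` | 0.4 Å | Gaussian width per water |
| `margin` | 4.0 Å | grid padding around the fragment (the 4σ kernel radius is added internally) |
| `peak_min_separation` | 1.0 Å | peaks closer than this merge, keeping the higher |
| `min_weight` | 0.05 | peak threshold in occupancy-equivalent units |
| resolution ≤ | 2.6 Å | curation: inclusive bound |
| waters/nt > | 1.0 | curation: exclusive bound |
| mismatches | 2 (< 24 nt), ⌊N/12⌋ (≥ 24 nt) | sequence-redundancy tolerance |

The density machinery replaces a crystallographic Fourier-averaging
toolchain with direct accumulation of normalized isotropic Gaussians
truncated at 4σ: the object computed — a band-limited water probability
density whose maxima are the hydration sites — is the same, with σ
playing the role of the pseudo-atom form-factor width. The peak
threshold is expressed in occupancy units (`min_weight` × the central
density of a point water of the pipeline's occupancy divisor), so the
same threshold means the same minimal occupancy regardless of block
population.

At prediction time each block water is reweighted to 1/n_steps of its
block before accumulation, which makes block-level and prediction-level
occupancies commensurable (prediction occupancies use divisor 1) and
prevents heavily populated conformers from drowning out rare ones.

## Numerical choices

- **Superposition** is the SVD form of the least-squares rigid fit with
  the determinant correction, so reflections can never be returned;
  near-collinear point sets (second singular value ≈ 0) are rejected.
  Six-atom selection ties are broken by (distance, residue slot, atom
  name) for determinism.
- **Peak refinement**: strict 26-neighbour local maxima above threshold
  are refined per axis by quadratic interpolation (never by more than
  half a voxel), then merged greedily in descending order of height.
- **Altlocs**: the highest-occupancy alternate location per atom is
  kept, ties by altloc letter. Hydrogens are parsed but excluded from
  every distance computation. Waters with zero crystallographic
  occupancy are retained (logged).
- **Chain breaks**: consecutive residues form a step only when the
  O3'–P distance is ≤ 2.5 Å — generous against the ~1.6 Å bond yet
  strict enough to exclude lattice neighbours. Modified nucleotides map
  to parents through an editable table; unmapped names break the chain.
- **C1'/O4'** are assigned to the backbone (sugar) category by covalent
  identity, although O4' also takes part in minor-groove bridges.
- **Boundaries** made exact: reliability at ≥ 800 waters inclusive;
  occupancy radius inclusive at 1.0 Å; curation resolution inclusive at
  2.6 Å and waters-per-nucleotide exclusive at 1.0.
- Sites with occupancy > 1 (merged dense clusters) are reported with a
  warning, never clamped.

## Design choices where the design was open

- *Sequence redundancy for unequal lengths*: best ungapped sliding
  alignment of the shorter inside the longer, thresholded by the
  shorter length — cheap and deterministic. Reverse complements are
  not folded together.
- *Mismatch rule for long sequences*: ⌊N_nuc/12⌋, continuous with the
  2-mismatch rule at 24 nt; configurable.
- *Reference dinucleotides*: externally supplied class representatives
  are used when given; otherwise the medoid contributing step (minimum
  summed pairwise r.m.s.d.) anchors the block frame.
- *Transfer quality gate*: without one, distorted local frames smear
  the density; 0.75 Å on the six-atom r.m.s.d. rejects only genuinely
  deviant frames. Waters whose six alignment atoms cannot be matched in
  the reference are dropped and logged.
- *NANT steps* are skipped (and logged) at prediction time rather than
  down-weighted; unreliable blocks are skipped by default, overridable.
- *Dual-category waters* (within 3.4 Å of both a base and a backbone
  atom) contribute to both grids, mirroring the independent category
  criteria.

## The synthetic generator

The generator exists so that every pipeline stage is testable without
downloads. It builds idealized single-stranded B- or A-form DNA from
internal coordinates: ideal bond lengths and angles, canonical
backbone/glycosidic torsions, chained by natural-extension-reference-
frame placement. The deoxyribose is a planar regular pentagon placed on
the C4'–C3' edge with its orientation chosen for near-tetrahedral
exocyclic angles (real sugars pucker; the flat ring is an accepted
idealization), and bases are planar idealized polygons. Every
consecutive step of a chain is congruent, so single-combination corpora
are easy to construct. Hydration sites are planted at hydrogen-bonding
distance (2.8 Å) off base and phosphate/sugar anchor atoms; each
structure draws a water per site with probability equal to the planted
occupancy, jittered isotropically, and the whole assembly is scattered
by uniform random rigid transforms. Output is deterministic under a
fixed seed, byte-identical on disk.

What the generator does **not** emulate: duplex base pairing and
groove geometry, sequence-dependent hydration (sites are placed by
geometry, not chemistry), ions, second-shell water networks,
resolution-dependent water incompleteness, and correlated coordinate
error. Passing the recovery tests therefore demonstrates that the
machinery — association, transfer, density, peak picking, occupancy
accounting, prediction overlay and evaluation — is correct and
self-consistent, not that real DNA hydration is predicted with any
particular accuracy; that depends on a real curated corpus.

The synthetic study conditions used by the test suite and the
acceptance script are: 100 contributing dinucleotides, four planted
sites with occupancies 0.9/0.6/0.4/0.2 and jitter σ = 0.25 Å, an
unseen rigidly transformed copy as the prediction target. At these
sizes the binomial sampling error of an occupancy is ~0.03–0.05, which
is why recovered occupancies are checked to ±0.1.

## Known limitations

- First shell only: the 3.4 Å category cutoff excludes second-shell
  features (e.g. the outer part of the minor-groove spine) by
  construction.
- The nearest-centroid conformer classifier is an admitted
  approximation for when external NtC assignments are unavailable; its
  labels depend entirely on the supplied centroid table.
- No ions, no B-factor modelling of waters, no energetic scoring.
- Occupancies of merged sites can exceed 1 and are reported as such.
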