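# Methods

`nanopept` models the design and early-stage co-assembly of minimal
tetrapeptide drug nanocarriers: acetylated Ac-X₁X₂X₃H peptides that
aggregate together with a cancer drug, Zn²⁺ and NO₃⁻ into charge-neutral
multicomponent particles. Histidine is pinned at position 4 as the Zn²⁺
coordination site; positions 1–3 are designable. This note records the
model, its assumptions, the parameters that matter, and the limits of what
the synthetic fixtures can show.

## Chemistry and charge bookkeeping

Side-chain charges are static pH-7 values (D/E −1, K/R +1, H 0). The
N-terminus is always acetylated (0 e); the C-terminus is either a free
carboxylate (−1 e) or an amide (0 e). Drug net charges are fixed constants
of the built-in specifications: EPI/DOX +1 (protonated amino sugar), MTX −2
(two glutamate carboxylates), MIT/5FU/CPT/CP 0, Orange G −2. These
assignments are an inference from the charge-neutral design arithmetic, not
a pKa calculation; protonation states and tautomers are out of scope.

The composition solver finds the smallest `n_zn ≥ min_zn` and `n_no3 ≥ 0`
with

    n_pep·q_pep + n_drug·q_drug + 2·n_zn − n_no3 = 0   (exactly).

`min_zn` defaults to 1 because every designed system carries Zn²⁺ for His
coordination and Zn-enhanced fluorescence. With 4 peptides and 2 drugs this
yields peptide:drug:Zn = 4:2:1 for the +1 drugs (carboxylate termini) and
the neutral drugs (amide termini), and 4:2:2 for MTX.

## Molecular representation

Peptides use a reduced representation: an acetyl-cap carbon; backbone N,
Cα, C, O per residue; one typed side-chain pseudo-atom per residue
(element, radius and donor/acceptor/hydrophobic/aromatic/charge flags from
a per-residue table); and a terminal carboxylate O (formal −1) or amide N.
Strand geometry is an idealized extended template (3.4 Å residue pitch,
±0.6 Å Cα pleat, carbonyl O offset 1.2 Å and amide N inset 0.7 Å on
alternating faces) laid out so that the antiparallel partner at the default
4.8 Å inter-strand spacing forms four backbone N···O contacts of 2.9 Å.
Hydrogens are not represented; hydrogen bonds are distance-only criteria.

Drugs are full heavy-atom models generated at load time by seeded
distance-geometry embedding (ETKDG) of stored SMILES; typing
(hydrophobic carbon, donor, acceptor, aromatic, formal charge) comes from
the molecular graph, radii from the periodic table. EPI and DOX are
epimers and share one constitutional graph here. Zn²⁺ is a single charged
atom (r = 1.39 Å); NO₃⁻ is planar with one Lewis-structure charge
assignment (N +1, two O −1).

## Scoring

The pairwise scorer acts on the surface distance d = |r| − Rᵃ − Rᵇ with a
hard 8 Å center-distance cutoff:

* attractive Gaussian: w_g·exp(−(d/0.8)²), w_g = −0.045 kcal/mol;
* steric repulsion: 0.8·d² for d < 0;
* hydrophobic term: −0.035 × linear switch (on below 0 Å, off above 2.5 Å),
  hydrophobic–hydrophobic pairs only;
* hydrogen bond: −0.6 × linear switch (on below −0.6 Å, off above 0 Å),
  donor–acceptor pairs only;
* Zn coordination: a separable radial well w_zn·exp(−((r−2.1)/0.4)²),
  w_zn = −2.0 kcal/mol, between Zn and His imidazole N or anionic O. This
  is a deliberate radial simplification of directional metal-coordination
  scoring.

The gauss/repulsion/hydrophobic/h-bond weights follow the published Vinardo
parameterization; all weights and shapes are config-overridable. A
molecule's association free energy is the sum of its pair terms with every
other molecule; the mean over drug copies is the design objective. The
bookkeeping identity Σ_molecules E = 2 Σ_pairs holds to 1e-9 relative and
is tested against a scalar double-loop oracle.

SASA uses Shrake–Rupley quadrature on a deterministic golden-spiral point
set (default 960 points/atom, probe 1.4 Å). Determinism buys exact
reproducibility at a cost: rotating a body moves it relative to the fixed
grid, so SASA is rotation-invariant only to quadrature resolution (≲0.5%
at 960 points), while translation invariance, energies and radius of
gyration are exact to numerical precision. Rg is mass-unweighted by
default (all atoms weight 1), with optional masses.

## Ordered assemblies and fixtures

`build_ips` deterministically stacks pocket units: one drug sandwiched
between two antiparallel peptide pairs. The upper layer is the z-mirror of
the lower so side chains on both outer faces point away from the pocket.
The drug is placed by its principal-axes frame (long axis along the
strands, thin axis across the gap); the layer separation starts at 10 Å
and expands until every drug/peptide atom pair keeps a ≥0.3 Å vdW surface
gap, so any built-in drug fits without steric overlap. Zn²⁺ sits 2.1 Å
beyond each His side-chain pseudo-atom along the Cα→side-chain direction;
nitrates continue outward along the same axis at 4 Å. Compositions always
come from the neutrality solver.

`build_ses_like` produces compact, partially disordered variants: molecule
centroids are scaled toward the global centroid by a compaction factor,
then each molecule gets seeded rigid-body jitter (translation bounded by
the perturbation in Å, rotation by 0.15 rad per Å), retried under a steric
guard of 0.7 × vdW-radius sum. Metals use 45% of their vdW radius in the
guard because Zn–N/O coordination bonds at ~2.1 Å are legitimately
sub-vdW.

`generate_random_snapshot` places all components of a neutral composition
with random orientation/position in a cubic box at a minimum
inter-molecule atom separation (default 5 Å), emulating the dispersed
starting states of early-stage co-assembly. `plant_clusters` chains
molecules into aggregates at a target contact distance on a widely spaced
grid, returning ground-truth membership for validating cluster detection.
These fixtures reproduce the designed component ratios and contact
topologies but not solvent, thermal motion, realistic conformational
ensembles, or assembly kinetics — passing tests demonstrate correctness of
the operators, not simulation realism.

## Sequence design

Each iteration proposes one mutation: the position is uniform over {1, 2,
3} and the replacement residue is drawn from a row-stochastic substitution
table (self-substitution excluded, optional temperature sharpening). The
shipped table is a half-bit softmax of BLOSUM62, P(b|a) ∝ 2^(S(a,b)/2),
stored as a data file so another published matrix can be dropped in. The
candidate is threaded onto every scaffold (the reduced backbone is
sequence-independent; side-chain typing changes), evaluated as the minimum
over (scaffold, drug pose) of the mean drug association energy, and
accepted only on strict improvement — ties reject, matching a
lock/unlock-on-improvement rule. Runs stop at the iteration budget
(default 500) or after 200 consecutive rejections; the stall criterion is
this package's concrete convergence choice. Re-visited sequences are
re-evaluated and the best energy per sequence is kept.

Consensus peptides are sequences appearing in every drug's runs (accepted
set by default; all-visited optionally). The consensus energy penalty is
the mean over drugs of the gap to that drug's best peptide:
penalty(p) = (1/D) Σ_d [E(p,d) − min_q E(q,d)] ≥ 0, zero iff best for
every drug; ranking is ascending with lexicographic tie-breaks. This
concrete penalty is the package's own formula choice. Aggregation
propensity is the sum of a named per-residue scale over all four
positions; the default scale is Chou–Fasman β-propensity (β-prone, Trp-rich
sequences score high), with Kyte–Doolittle hydropathy and an aromaticity
indicator also shipped.

## Assembly analysis

Two molecules are in contact when their minimum heavy-atom distance is
≤ 4.5 Å (configurable; reported in all outputs); clusters are connected
components of the contact graph. The KD-tree acceleration is exact and is
tested for equality with a dense-matrix BFS oracle. Encapsulation profiles
report per-size and cumulative-size percentages of each component kind in
clusters (singletons count as size 1, so the cumulative value at threshold
1 is 100% by definition). Composition ratios are normalized to a peptide
base of 4.

β-sheet assignment is a geometric stand-in for extended/β-bridge
assignment — four-residue peptides sit at the edge of standard secondary
structure assigners — flagging a peptide when some partner shares ≥2
inter-peptide backbone N···O contacts ≤3.5 Å and has a strand axis within
30° of parallel/antiparallel. A drug "mediates" two peptides when it
touches both within the contact cutoff; the three-body variant adds a Zn
contact; probabilities are mediating drugs over all drugs, overall and by
cluster size. The representative cluster is the largest in the final
frame, ties broken by lowest mean member association energy.
Energy–burial profiles pair each molecule's association energy with its
burial fraction, SASA in the assembly over SASA in isolation.

## Numerical and testing choices

All randomness flows through seeded `numpy` generators; identical seeds
give bitwise-identical snapshots and design histories. Test problem sizes
are deliberately small — random fixtures of ~15–30 molecules, 50-seed
design ensembles against a separable synthetic objective with a known
optimum, two-sphere SASA cases against a 10⁶-point Monte-Carlo oracle —
chosen so the whole suite re-derives every guarantee from scratch in
seconds while exercising the same code paths as larger systems.

## Known limitations

No explicit solvent, no dynamics, no entropy: the "association free
energy" is an empirical score, comparable across sequences and poses but
not an absolute binding free energy. Pose search is a small deterministic
orientation set, not docking. The reduced peptide representation cannot
express rotamers or backbone flexibility. Cluster analysis assumes whole,
unwrapped molecules (no periodic-boundary imaging). EPI and DOX are
indistinguishable to the scorer.
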