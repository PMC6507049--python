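# Methods

## The electrostatic model

All electrostatics is uniform-dielectric screened Coulomb (Debye–Hückel).
The potential of a formal point charge q at distance d is

    φ(d) = q e^(−κd) / (4π ε₀ ε_r d),   κ = √(2 N_A e² · 1000·I / (ε₀ ε_r k_B T))

with defaults ε_r = 78.4, I = 0.15 mol/L, T = 298.15 K (Debye length
≈ 7.85 Å). There is no grid Poisson–Boltzmann solver and no
protein-interior dielectric: the single-dielectric form keeps every
quantity closed-form, exactly superposable and bit-reproducible, at the
cost of ignoring desolvation and dielectric-boundary focusing. Patch
*areas* computed this way are therefore model-dependent; the ratio of a
variant's patch to a threshold calibrated under the same model is the
meaningful output. All conversion constants are pinned in one table
(`_constants.py`); internal units are mV for potentials, kJ/mol for
energies, Å for distances.

Formal charges at pH 7 sit on canonical atoms, split across chemically
equivalent pairs to avoid orientation artifacts: Asp −0.5/−0.5 on
OD1/OD2, Glu on OE1/OE2, Arg +0.5/+0.5 on NH1/NH2, Lys +1 on NZ, +1 on
the N-terminal nitrogen, −1 split over the C-terminal carboxylate
oxygens. Histidine is neutral in the fixed-charge patch map (model pKa
6.3 < 7) but titrates in the stability model — this separation keeps the
patch calculation pH-free while the titration model owns pH dependence.

## Surface and patches

The surface is solvent-accessible: each atom contributes a deterministic
golden-spiral point set on its expanded sphere (united-atom radius +
probe, probe 1.4 Å, radii C 1.9 / N 1.7 / O 1.5 / S 1.85 Å), and dots
inside any other expanded sphere are culled (Shrake–Rupley). A surviving
dot carries area 4π(r+probe)²/dots_per_atom, so patch sizes are areas,
not dot counts, and are density-independent to first order (doubling the
density moves total area by < 1 %). Dots are linked into a neighbour
graph by a Euclidean cutoff, by default 2× the mean nearest-neighbour
spacing clamped to [0.5, 5] Å — stable across densities.

Dots are classed by potential: positive (> +25 mV), negative (< −25 mV),
non-charged (closed interval between). Strict inequalities at the
contours are a determinism convention; boundary values are measure-zero
in float fields. Patches are connected components of the neighbour graph
restricted to one class; posQmax is the largest positive patch's area. A
residue "belongs" to a patch if it parents at least one member dot, which
defines the candidate set for mutation screening.

The solubility call is posQmax/threshold with "insoluble" strictly above
1.0. No universal threshold ships: the calibration data are external. 
`calibrate_threshold` rebuilds one from any labelled (posQmax, label)
table by exhaustive midpoint scan maximising balanced accuracy (ties to
the smallest threshold); `tune_threshold_on_reference` implements the
one-parameter alternative of anchoring a reference structure at a known
ratio. The supplementary positive + non-charged signal is reported as the
(ratio, hydmax) pair without its own threshold.

## Sidechain replacement and screening

Mutations preserve N, CA, C, O exactly (and CB when both residues have
one); the new sidechain comes from the ideal residue geometry in
biotite's chemical-component tables, mapped onto the backbone by
three-point superposition. A small rotamer library (χ1 ∈ {−60°, 180°,
60°}; χ2 additionally {±90°} for rings) is scanned and the rotamer with
the fewest heavy-atom clashes (pair distance < 0.7 × radius sum) against
the rest of the structure wins, ties to library order — deterministic,
and adequate because formal-charge positions dominate the downstream
electrostatics. No minimisation, repacking or backbone relaxation.
Aspartate is the default negative-introduction residue (shorter sidechain
than glutamate). The patch screen re-runs the *entire* pipeline per
mutant — no frozen-surface shortcut — so shape-changing mutations like
Phe→Asp are handled correctly.

## Titration and pHstab

Each titratable site (Asp 4.0, Glu 4.4, His 6.3, Lys 10.4, Arg 12.0, Tyr
9.6, Cys 8.3, N-term 7.5, C-term 3.8; disulphide-bonded cysteines
excluded, SG–SG < 2.5 Å) carries its model pKa as the intrinsic pKa —
there is no Born/desolvation shift, a deliberate simplification: the
folded state differs from the unfolded one only through the
charge–charge matrix W. The microstate energy is

    E(x, pH) = Σᵢ xᵢ ln10 · RT (pH − pKaᵢ) + Σᵢ<ⱼ Wᵢⱼ qᵢ(xᵢ) qⱼ(xⱼ)

with q = x − 1 for acids, q = x for bases. Systems with ≤ 20 sites are
enumerated exactly (2^N partition function, logsumexp); larger ones use
single-flip Metropolis Monte Carlo (default 10⁴ sweeps after 10³ burn-in,
mandatory seed). Fractions are accumulated with the Rao-Blackwellised
heat-bath estimator (each site's exact conditional probability given the
rest), which brings the 10⁴-sweep error comfortably under 0.01.

Free energies are G = −RT ln Z on a pH grid (default 0–14, step 0.25).
The Monte Carlo path anchors G at the acidic end of the grid — exactly
when enumerable, otherwise by thermodynamic integration of ⟨E_W⟩ over a
coupling constant scaling W from 0 — and extends along the grid by
integrating the bound-proton count, dG/dpH = ln10 · RT ⟨n_H⟩
(trapezoidal). The unfolded state is the same site list with W ≡ 0,
which is analytic (per-site Henderson–Hasselbalch). Then

    pHstab(pH) = G_folded(pH) − G_unfolded(pH),

the free-energy contribution of the folded state's ionisable-group
interactions; negative = stabilising. Identical models give exactly zero;
an Asp/Lys contact pair is stabilising at pH 7 and a Lys/Lys pair
destabilising, which fixes the sign convention.

## Structure handling

PDB input goes through gemmi. Waters and non-polymer HETATMs are dropped,
hydrogens ignored (united-atom radii), alternate locations resolved to
the highest-occupancy conformer with ties to the first altloc. Sequence
edits (`K24N`-style tokens) are validated against the residue actually
present — re-applying an applied edit errors rather than silently
passing. Missing charge-center atoms fall back to the sidechain centroid
with a warning.

Orthologue models are sidechain-replacement only: matched alignment
columns mutate, target gaps delete the residue, template gaps (target
insertions) are flagged unmodelled; no loop building. Coverage < 0.8
marks a model low-confidence. This keeps patch and stability values
comparable on the shared core while refusing to invent geometry.

## Synthetic data

The fixture generators (`fixtures.py`) emit single spheres, dumbbells,
ideal helices with programmable charged residues, and charge lattices as
ordinary PDB text, together with expected-value records computed from
closed forms at generation time (sphere and two-sphere areas, Coulomb
potentials, patch topology). They exercise the real parsing and pipeline
code paths; what they do not emulate is real-protein irregularity —
heterogeneous packing, partial burial of charges, crystallographic noise.

The synthetic EPO model (`synthetic_epo.py`) threads the real 166-residue
mature human EPO sequence (crystal-analogue form K24/K38/K83/N121/S122;
the five documented edits restore the native cDNA sequence) onto an
idealised up-up-down-down four-helix bundle. Helices and connectors are
built as locally-helical tubes along a continuous guide curve whose
routing encodes only documented features of the fold: the C7–C161 and
C29–C33 disulphides and the packing of the F48 region against helix D
near L155. It reproduces the fold's charge topology — the helix-D
lysine/arginine cluster forms the dominant positive patch, E13K enlarges
it, R150D/F48D shrink it — but its absolute patch areas and the finer
ordering of similarly-sized variants are properties of the idealised
geometry, not of the crystal structure. Tests passing on it demonstrate
the machinery, not numeric parity with measurements on the experimental
structure.

## Numerical and design choices

* Dot placement, rotamer search, alternate-location and tie-breaking
  rules are all deterministic; the only stochastic component is the
  Monte Carlo titration, which takes an explicit seed and is
  bit-reproducible per seed.
* Problem sizes in the shipped tests and the acceptance script are chosen
  for quick, exact cross-checking: oracle surfaces stay under 2000 dots
  so the brute-force BFS partition is exhaustive; Monte Carlo/exact
  comparisons use ≤ 12 sites so 2^N enumeration is the reference; the
  synthetic EPO runs use the default 256 dots/atom (≈ 33 000 dots before
  culling).
* The interaction matrix rejects sites closer than 0.5 Å and potentials
  are never evaluated within 0.1 Å of a charge; surface dots sit at least
  a probe radius away from any charge center by construction.
* Degenerate inputs: empty site lists titrate trivially (G ≡ 0); fully
  buried atoms contribute no dots; duplicate atoms at identical positions
  contribute surface area once.

## Known limitations

Uniform dielectric (no desolvation or interior/exterior boundary), no
conformational relaxation of mutants, intrinsic pKas equal to model pKas,
no glycosylation, and the synthetic EPO stand-in described above. The
threshold is only as good as the calibration data supplied to it.
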