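# Methods

`uimtools` analyses the structural duality of ubiquitin-interacting motifs
(UIMs): short linear motifs that bind ubiquitin as an amphipathic α-helix
but can be largely disordered in their free state. The package implements
three analysis stages and a synthetic-data layer that emulates the inputs
those stages expect (MD-style conformational ensembles, NMR chemical-shift
depositions, and sequence databases).

## Conformational-ensemble descriptors

An ensemble is a set of backbone conformers of one peptide, stored as
per-residue (φ, ψ) dihedrals plus N/Cα/C/O/Cβ coordinates and per-frame
weights (uniform unless stated).

**Helix assignment.** A residue is helical in a frame when its (φ, ψ) fall
inside the windows φ ∈ [−100°, −30°], ψ ∈ [−77°, −17°] *and* it belongs to
a contiguous in-window run of ≥ 4 residues. This dihedral-window surrogate
replaces hydrogen-bond-based dictionaries (DSSP-style α/3₁₀/π classes),
which cannot be evaluated from dihedral-only input; windows and the
minimum run length are configurable. Chain termini lack a φ or ψ and are
never assigned helical. Per-residue helicity is the weighted fraction of
frames assigned helical; the persistence profile adds, per residue, the
mean length (in frames) of maximal consecutive-helical runs along the
trajectory, and is defined only for uniformly weighted (trajectory-order)
ensembles.

**alphabeta CV.** For ψ angles in radians,
`alphabeta = Σᵢ ½(1 + cos(ψᵢ − ψ_ref))` with ψ_ref = 0.7854 rad by
default. The value lies in [0, N] and equals N iff every ψ ≡ ψ_ref
(mod 2π); percentage mode reports 100·value/N. All N − 1 defined ψ angles
of an N-residue chain enter the trajectory version. Note the sign
convention: the canonical α-helix ψ is ≈ −47°, while the default
reference is +45°; the default follows the value commonly used to bias
toward helix-like ψ in enhanced-sampling setups and is deliberately not
flipped — pass `CVParams(psi_ref=...)` to change it. Ensemble windows in
alphabeta (defaults 9–17, 18–23, 24–30, 31–34) are closed intervals;
selection renormalises weights and preserves frame order, and an empty
window is a valid (logged) outcome.

**Subset RMSD / bound-like fraction.** RMSD to a reference conformation is
computed after least-squares superposition (SVD Kabsch with reflections
excluded) on an explicit atom subset: all N/Cα/C/O of a motif interval
plus named extra atoms — for the 15-residue UIM window 336–350 plus the
Cβ of the conserved Ala343 this is 61 atoms. Atom order is canonical
(ascending residue; N, Cα, C, O; then extras) so results are reproducible
across readers. The bound-like fraction is the weighted fraction of
frames within a threshold (default 3.0 Å) of the reference.

## Chemical-shift analysis

**Reduced χ².** Agreement between calculated and experimental shifts is
`χ²_red = (1/N) Σ (δ_calc − δ_exp)² / σ²(nucleus)` over the N common
(residue, nucleus) pairs, with σ the per-nucleus standard deviation of
the shift predictor (defaults: Cα 0.9, Cβ 1.1, C′ 1.1, N 2.5, H 0.5,
Hα 0.3 ppm — configurable; these are plausible predictor accuracies, not
fitted values). χ²_red is 0 iff the sets agree exactly and has mean 1
when deviations are i.i.d. N(0, σ²).

**Helix populations.** Secondary shifts are Δδ = δ_obs − δ_rc with a
packaged random-coil table. The per-residue helix population is
`f = clip((Δδ_Cα − Δδ_Cβ)/(offset_Cα − offset_Cβ), 0, 1)` with full-helix
offsets Cα +2.8, Cβ −0.5 ppm, smoothed by a centred 3-residue mean
(configurable; 1 disables). This is a deliberately simple Cα/Cβ
secondary-shift estimator — trained predictors such as δ2D are *not*
re-implemented, and reports label the estimator as a surrogate. Residues
lacking Cα or Cβ (glycine has no Cβ) are excluded from motif means and
counted. A motif is classified **helical** when its mean helix population
exceeds 0.3 and **disordered** below 0.1 (strict inequalities; boundary
values are intermediate), the same decision thresholds used with
predictor-derived populations.

NMR-STAR v3 depositions are read through `gemmi`'s STAR parser
(assigned-chemical-shift loops, numbering taken verbatim); a simple TSV
dialect is supported for synthetic and hand-made tables.

## Motif scanning and enrichment

Patterns are dash-separated positional classes (`x` any residue, `[..]`
a class, bare letter a literal, `(1,2)` a one-or-two-residue gap; the
symbolic consensus tokens `Ac`, `Phi`, `Ala`, `Ser` are also accepted,
with the hydrophobic set Φ = {A, I, L, M, F, V, W} by default). The
disordered-UIM pattern compiles to 17 positions with one variable gap
(window 17–18). Scanning reports every matching start position
(overlaps allowed); at a fixed start the shortest gap expansion wins.
Both raw hit counts and distinct-sequence counts are reported.

Enrichment uses a composition-preserving null: each sequence is
independently residue-shuffled, the database rescanned, and
`p = (1 + #{null ≥ observed}) / (1 + n_shuffles)`. Shuffling the scanned
database itself (rather than drawing a separate random database) makes
the null exactly composition- and length-matched; a user-supplied null
database can be scanned instead.

**Helical wheel.** Residue k (1-based) of a window projects to
(k−1)·100° mod 360°, the azimuth of an ideal 3.6-residue-per-turn helix.
A face is the set of residues within a half-width (default 40°) of a
centre residue. The β-branched report lists Val/Ile/Thr positions with
their wheel angles and angular distances to the conserved Ala/Ser face
and to the nearest acidic residue — descriptive output only, no score.

## Synthetic-data model

**Ensembles.** Helix/coil states are drawn per frame from a
heterogeneous first-order Markov chain along the sequence whose
transition probabilities are solved position-by-position so that the
per-residue helix marginals equal the target profile exactly; the
Zimm–Bragg-like nucleation penalty σ (default 0.05) sets the
adjacent-residue correlation ρ = max(0, 1 − σ), clamped wherever the
exact-marginal solution would leave [0, 1]. Cooperativity therefore
redistributes segment lengths without moving marginals — chosen over a
rejection-corrected segment model because only the marginals are part of
the generator's contract, and the closed-form chain honours them without
resampling. Helical residues draw (φ, ψ) from Gaussians centred on
(−57°, −47°) with 8° jitter; coil residues draw uniformly from
φ ∈ [−180°, −40°], ψ ∈ [60°, 180°] ∪ [−180°, −150°]. The coil basin is a
documented convention (a broad PPII/extended region), chosen to fall
cleanly outside the helix-assignment windows; real disordered ensembles
also populate bridge and left-handed regions that this two-basin model
omits. Coordinates are built by sequential natural-extension placement
with fixed ideal internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å, ω = 180°, Cβ at ideal L-tetrahedral geometry, absent for
Gly), so consecutive Cα–Cα distances are ≈ 3.8 Å and φ/ψ round-trip
through the coordinates to < 10⁻³ degrees.

**Shifts.** δ(i, nucleus) = rc(aa_i) + f_i·offset(nucleus) + N(0,
noise_sd), with the packaged random-coil table and the offsets above;
default noise 0.1 ppm. Because the downstream estimator inverts exactly
this forward model, shift round-trip tests validate the plumbing and the
thresholds, not the physical accuracy of any random-coil table.

**Sequence databases.** Background residues i.i.d. from a composition
table (uniform by default); planted motif instances overwrite a random
window in distinct sequences; records carry ids `synth_%05d`. The
shuffle used by the enrichment null is the same per-sequence permutation
described above.

All generators are pure functions of (inputs, seed).

**What passing tests do and do not show.** Synthetic ensembles have
ideal geometry, two dihedral basins and exact two-state residues; real
trajectories have correlated frames, bridge/turn states and non-ideal
geometry. Synthetic shifts match the estimator's forward model; real
depositions carry referencing offsets and sequence-dependent random-coil
corrections this package does not apply. Parameter-recovery results
therefore certify the analysis chain's correctness, not its accuracy on
experimental data.

## Problem sizes and numerical choices

Default study sizes: 2,000-frame ensembles of the 56-residue demo
construct for parameter recovery (binomial SE ≈ 0.011 per residue);
100-sequence, length-60 databases with 30 planted motifs and 200
shuffles for enrichment; 10,000 σ-scaled Gaussian deviations for χ²
calibration. The demo construct is synthetic: a UIM3-like 56-mer
(numbering 306–361) carrying the canonical motif features (acidic
E336/E337/D338, hydrophobic L340, invariant A343/S347, β-branched
V344/T345/T350) in a polar disordered flank.

Ties and degenerate cases: superposition excludes reflections by
flipping the smallest singular direction (for collinear sets this picks
the smallest-angle proper rotation); CV windows are closed so boundary
values belong to the window, and the four default windows are pairwise
disjoint while real-valued CVs between windows fall to the complement;
classification at exactly 0.3/0.1 is intermediate; the enrichment ratio
is 0 when nothing is observed and infinite when the null mean is 0 with
observed hits.

## Known limitations

- The helix assignment is dihedral-only; 3₁₀/π helices and H-bonded
  kinked helices are approximated by the window + run-length rule.
- The helix-population estimator uses only Cα/Cβ; nuclei-rich
  depositions carry information it ignores.
- Persistence is reported as occupancy plus mean run length; other
  persistence definitions (e.g. autocorrelation-based) are not provided.
- Metadynamics reweighting is out of scope; ensemble weights default to
  uniform.
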