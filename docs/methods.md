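# Methods

## Model and procedure

modekit treats a structure as the minimum of a harmonic energy surface.
The elastic network connects every site pair with separation
R_ij ≤ R_c by a Hookean spring, V_ij = (k_ij/2)(r_ij − R_ij)²; the cutoff
test is the closed inequality R² ≤ R_c². The mass-weighted Hessian D is
assembled spring by spring: each spring contributes the rank-1 3×3 block
−k·(R̂⊗R̂) off-diagonal, its negation to both diagonal blocks, and every
(i,j) block is divided by √(m_i m_j). Unweighted row sums therefore vanish
to machine precision (rigid translations cost nothing) and D is symmetric
positive semidefinite. Eigenvalues carry kcal mol⁻¹ Å⁻² Da⁻¹ and convert to
angular frequencies via ω²[s⁻²] = λ × 4.184×10²⁶ (kcal→J, Å⁻²→m⁻²,
Da·N_A = 1 g/mol); the factor is validated in the tests against a
closed-form one-oscillator fixture.

The GNM is the isotropic one-dimensional counterpart: the Kirchhoff
(contact Laplacian) matrix with −K off-diagonal for contacts, contact
degree on the diagonal, one zero mode when connected.

The RTB projection builds, per block, three mass-weighted rigid
translations and up to three rigid rotations about the block's centre of
mass, orthonormalized by SVD with singular columns dropped at relative
tolerance 1e-10 (single-atom and collinear blocks have fewer than six rigid
degrees of freedom). The projected problem PᵀDP is solved densely and the
eigenvectors are expanded back through P; because P has orthonormal
columns the expansion preserves orthonormality, and the explicit
renormalization is a no-op guard. RTB eigenvalues are variational upper
bounds on the full spectrum (asserted as Rayleigh interlacing in the
tests); with one atom per block they reproduce the full spectrum exactly.

Trajectory PCA removes rigid-body motion by mass-weighted Kabsch
superposition, iterated with the mean structure as reference until the
mean moves < 1e-6 Å RMS (first-frame reference available by flag), then
diagonalizes F = (1/n)Σ m¹ᐟ²Δx Δxᵀ m¹ᐟ². The population divisor n is the
default (the expectation in the definition carries no estimator
correction); n−1 is switchable. Variances Q² map to pseudo-frequencies
ω = √(kT/Q²) so PCA modes flow through every downstream analysis;
zero-variance modes get infinite pseudo-frequency and are excluded from
thermodynamic sums with a warning.

## Thermodynamics and units

The vibrational free energy and entropy use the quantum harmonic
oscillator: G_v = −kT ln[1/(1−e^(−x))] and
S_v = k[x/(e^x−1) − ln(1−e^(−x))] with x = ℏω/kT. All molar quantities use
k = 8.314 J mol⁻¹ K⁻¹; ℏ = 1.05457148×10⁻³⁴ J s is multiplied by
Avogadro's number internally so x is dimensionless in molar units. The
Schlitter per-mode value is the standard upper bound
S'_v = (k/2)ln[1 + (e·kT/ℏω)²], which the tests verify dominates S_v over
a log-spaced frequency grid. Default temperature is 300 K wherever a
temperature enters (it is not part of the network model itself).

B-factors follow B_i = (8π²/3)·Σ_v kT·e_i²(v)/(m_i ω_v²) in Å², evaluated
in native ENM units (kT in kcal/mol against the raw eigenvalue), with the
same mass convention used to build the network. The default analysis
window is modes 7–31 (1-based): the six rigid modes are skipped and the 25
lowest nonrigid modes kept; ranges including a zero mode raise rather than
silently diverge. Collectivity κ_v is the exponential Shannon entropy of
the normalized per-atom squared amplitudes divided by N, with the x·log x
→ 0 limit for zero-amplitude atoms. The cross-correlation map is computed
exactly as the unweighted normalized dot-product sum over the window; an
amplitude-weighted variant (each mode scaled by kT/ω²) is available behind
a flag and off by default. Distance fluctuations apply the raw eigenvector
as a displacement and divide by the native eigenvalue, as the formula is
printed; they are not mass-unweighted.

## Selection and I/O conventions

PDB parsing is fixed-column; unparseable ATOM records raise with the line
number. Alternate conformers keep the first-listed location. Hydrogens are
dropped by default (element column, falling back to the leading letter of
the atom name). Cα selection keeps atoms named CA, plus C4'/C1' (and the
older C4*/C1* spellings) in DNA mode. Masses: unit (1 Da, the default —
mass weighting has little effect on low-frequency modes), atomic (bundled
average element masses keyed on the PDB element column, falling back to
the first character of the atom name), or residue (bundled average
amino-acid/nucleotide residue masses on the Cα site; only meaningful with
Cα selection). Atom order in the structure defines the index of every
matrix row; 0-based internally, 1-based in files and CLI flags.

Trajectories are read from four text dialects (multi-model PDB, Amber
ASCII with 8-character fixed fields, DL_POLY HISTORY with levcfg 0,
GRO series with nm→Å conversion); truncated final frames are dropped with
a warning, atom-count mismatches raise. Binary engine formats are out of
scope for the core; any adapter producing the same in-memory Trajectory
can feed the pipeline. Periodic unwrapping shifts each atom to the image
nearest its previous-frame position (first frame: nearest the reference),
with an exact half-box jump resolved toward no shift. The eigenfile is a
plain-text container (header `nmodes N natoms M weighting <w>`, per-mode
eigenvalue line plus components at 17 significant digits) that round-trips
float64 bit-exactly; mode kind is inferred (N components per mode → GNM)
or stated by the caller for PCA files. The NMWiz `.nmd` writer sets each
mode's scale to the RMS atomic amplitude √(Σe²/N) of the unit-norm
eigenvector.

## Synthetic data

The fixture generator produces deterministic toy systems: Cα chains at
3.8 Å spacing, ideal helices (1.5 Å rise, 100°/residue, 2.3 Å radius),
compact random blobs with a 3.8 Å minimum site separation, and
deliberately disconnected two-cluster systems 30 Å apart (beyond twice the
default cutoff, guaranteeing twelve zero modes). Harmonic trajectories are
i.i.d. equilibrium samples: each frame draws independent Gaussian mode
amplitudes of variance kT/ω². This reproduces the equilibrium
distribution that covariance analysis consumes but has no time
correlation, solvent, anharmonicity or sampling error beyond finite n —
passing the closure tests shows the PCA machinery is correct, not that
real MD converges. Test problem sizes (20–30 sites, 10⁴ frames) keep the
whole suite in seconds while leaving eigenvalue gaps large enough for mode
identification; frequency-recovery assertions apply only to modes whose
relative eigenvalue gap exceeds 10%, since eigenvectors of nearly
degenerate pairs mix under sampling noise.

## Numerical choices and limitations

Near-zero eigenvalues are counted below 1e-9 of the spectral scale (the
row-sum norm, an upper bound on the spectral radius, so the count is
stable when only a subset of modes is solved). Full diagonalization
returns all modes up to 1000 sites and the lowest 106 beyond. Six zero
modes are expected for 3-D networks and one for GNM; more triggers the
disconnection diagnostic, fewer (collinear geometries) a degeneracy
warning. Coincident atoms in a spring raise (undefined direction), as do
collinear frames in superposition (underdetermined rotation). The Hinsen
spring variants default to the exponential k₀e^(−r²/r₀²) with r₀ = 3 Å and
k₀ = 86 kcal mol⁻¹ Å⁻², and a two-regime fitted law (linear below 4 Å,
r⁻⁶ above) converted from kJ/mol/nm units; both are parameters, not
constants. The power-decay exponent defaults to 2 and the decay applies
inside the cutoff window. B-factor painting clamps values to the
six-column PDB field with a warning. No energy minimization, secondary
structure computation, mmCIF parsing, or rendering is performed; secondary
structure for blocking comes from HELIX/SHEET records or a user-supplied
one-letter string, and visualization is delegated to NMWiz/VMD via the
`.nmd` export.
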