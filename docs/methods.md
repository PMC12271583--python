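# Methods

This note records the scientific conventions, numerical choices and known
limitations behind `cryolabel`'s pipeline.

## Grid model and coordinate transforms

A map is a 3-D scalar field stored `(i, j, k) = (z, y, x)` (MRC section /
row / column order) with a physical origin `(origin_x, origin_y, origin_z)`
at the corner of voxel (0, 0, 0) and per-axis voxel sizes in Å. The
forward atom-to-voxel transform is plain floor division per axis. The
inverse transform uses the voxel-**center** convention,
`origin + (idx + 0.5)·voxel`, chosen so that forward∘inverse is the
identity on every in-bounds index — the invariant the label maps rely on.
Floor truncation loses up to one voxel of positional accuracy; the 6 Å
neighborhood labeling (below) is the compensating mechanism.

Resampling to the standard 1 Å voxel is trilinear at output voxel centers,
zero-filled outside the input extent (cryo-EM maps are solvent-padded, so
zero is the natural fill), with output dims `ceil(extent/target)` per axis
and the origin unchanged. Trilinear sample points are taken at voxel
centers; whether ChimeraX's resample uses corner or center sample points is
not documented, so sub-voxel differences from ChimeraX-standardized maps
are possible. Fourier-space (band-limited) resampling is out of scope.

## MRC normalization

Deposited maps disagree on two header conventions. Axis correspondence
(`mapc/mapr/maps`) is normalized at read time by permuting the payload to
canonical z/y/x order. The physical origin is taken from the float `ORIGIN`
words when any component is nonzero, otherwise from the integer start
indices times the voxel size; both dialects can be forced explicitly. Voxel
sizes derive from `cella / (mx, my, mz)` per physical axis. Files are
written canonically (x fastest, mode 2 float32, ORIGIN populated,
statistics recomputed); integer label maps default to mode-2 float holding
exact small integers for compatibility with common training loaders, with
an int8 (mode 0) option.

## Structure handling

Biological assemblies (`.pdb1`) may replicate a chain across `MODEL`
blocks; all models are concatenated as assembly copies. Waters are dropped
by default; other hetero atoms are kept (deposited models may lack ligands
and glycans, but when present they are real density and are labeled).
Alternate locations keep the highest-occupancy record, ties resolved by
file order. mmCIF is not supported.

Atom-type codes: Cα = 1, Cβ = 2, backbone carbonyl C = 3, oxygen = 4,
nitrogen = 5, everything else 0. Codes 1–3 additionally require a standard
amino-acid residue in a non-HETATM record, so a calcium ion (also named
"CA") stays 0. Nucleic-acid O/N atoms receive codes 4/5 by element; their
carbons and phosphorus are 0.

## Simulated density

Each atom deposits an isotropic Gaussian with FWHM equal to the nominal
resolution R (σ = R/(2√(2 ln 2))), unit integral, truncated at 4σ
(truncation loses < 0.1 % of mass, tested). Atoms are weighted uniformly by
default; an atomic-number weighting is available. This mirrors the Gaussian
mode of real-space convolution simulators such as Situs `pdb2vol`; exact
numeric parity with any one simulator's output is not claimed, since kernel
amplitude conventions differ between tools. Electron scattering factors and
B-factor-dependent widths are deliberately out of scope. The kernel
resolution should be set to the entry's reported resolution when known; the
synthetic fixtures use 2.0 Å. A warning (not an error) is raised when
σ < voxel/2, where the grid undersamples the kernel.

## Label generation

Three zero-initialized grids share the standardized experimental map's
dims, origin and voxel. Per atom, the floored index must be in bounds on
the experimental grid *and* the atomic coordinate must fall inside the
simulated map's physical extent (dual validation — meaningful when the
simulated map came from an external tool on its own bounding grid; when
simulated internally on the aligned grid the two checks coincide). An atom
failing dual validation contributes nothing, neighbors included.

Neighborhoods are the in-bounds voxels whose **centers** lie within the
radius (default 6 Å, configurable) of the atomic coordinate — centers, not
corners, because the atomic coordinate is the only exact quantity.
Classification: direct voxel 1, neighbors 2, with 1 taking precedence at
contested voxels. Atom-type: direct voxels only; collisions resolved
last-writer-wins except 0 never overwrites a nonzero code (a deterministic
rule; the neighbor chemistry is ambiguous by construction, so neighbors
stay 0). Regression: the simulated density at each labeled voxel — copied
by index when the grids are aligned, trilinearly sampled at the voxel
center otherwise — which makes `regression = simulated × (classification >
0)` exact in the aligned case (asserted on every output). Neighbor voxels
are clipped by the experimental extent only, not additionally by the
simulated extent.

## FSC validation

Unmasked FSC per shell: `Re Σ F_a F_b* / √(Σ|F_a|² Σ|F_b|²)` over discrete
frequencies binned by radial magnitude. Shell width defaults to one
Fourier voxel, 1/(N·voxel) with N the largest dimension; the DC term is
excluded and shells are reported up to Nyquist (1/(2·voxel)). Isotropic
voxels are required (the dataset is standardized to 1 Å); anisotropic
grids raise an error rather than silently mixing frequency scales. The
resolution at a threshold is linearly interpolated between the bracketing
shells; a curve that never falls below the threshold reports the Nyquist
limit 2·voxel (for hand-built curves with no grid, the last shell), and a
curve already below threshold in its first shell reports ∞. Model maps use
the Gaussian kernel above, not electron scattering factors as
`phenix.mtriage` does, so agreement with phenix-computed values is
approximate (order of ±0.3 Å / one shell), not bit-exact. Both maps are
z-score normalized before the FFT purely as a numerical guard; FSC is
scale-invariant. Half-map FSC, masking and local resolution are out of
scope.

The dataset-level statistic is the percent improvement of mean FSC-0.5
resolution, `100·(mean_before − mean_after)/mean_before`, implemented in
`summarize_resolutions` / the `summarize` CLI over a per-entry manifest.

## Curation rules

From a local metadata table (network harvesting is out of scope): keep a
record iff it has a biological assembly, a resolution determined by the
FSC-0.143 criterion, and 1 ≤ resolution ≤ 4 Å; then keep one entry per
assembly — the best (lowest) resolution, ties broken by the smallest EMDB
accession. The tie-break and winner rule are this package's choice; the
original curation did not state which redundant entry was retained. A blank
resolution method is accepted (it cannot be shown not to be FSC-0.143);
only an explicitly different method is rejected. Resolution-based
train/validation/test splitting is recommended downstream but not
implemented here.

## Synthetic fixtures and what they show

The fixture structure is an ideal poly-alanine α-helix (rise 1.5 Å,
twist 100°, Cα 2.3 Å off axis; N, C, O, Cβ at fixed ideal offsets rotated
per residue — textbook geometry, adequate because the pipeline depends on
coordinates and elements, not on chemical realism). The default bundle
uses 20 residues (100 atoms) on a ~41×20×20 grid at 1 Å: large enough for
stable FSC shells, small enough that the full suite runs in seconds. The
"experimental" map adds seeded white Gaussian noise (default σ = 0.05
density units, against a clean-map peak of ~0.17) emulating shot/digital
noise, plus 3 Gaussian blobs (σ = 2 Å, amplitude half the map peak) placed
preferentially in the outer 20 % shell of the box as off-particle
structural-noise surrogates.

These fixtures exercise every code path (alignment, dual validation,
neighbor clipping, FSC degradation with noise) but do not emulate CTF
effects, solvent flattening, B-factor variation, masking artifacts or the
spectral signature of real reconstructions — passing tests demonstrate the
correctness of the labeling geometry and statistics, not performance on
deposited maps.

## Numerical choices

* Accumulation in float64, storage in float32 (MRC mode 2).
* Kernel truncation at 4σ balances mass fidelity (<0.1 % loss) against the
  per-atom window size.
* FSC shells with zero voxels or zero power are dropped; correlations are
  clipped to [−1, 1] against rounding excursions.
* Resample dimension count guards against float noise in `extent/target`
  with a 1e-9 slack before the ceiling.
* Determinism: every stochastic element (noise, blob placement, random
  test grids) draws from `numpy.random.default_rng(seed)`; reruns at one
  seed are byte-identical, which the test suite asserts on the full
  pipeline output.
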