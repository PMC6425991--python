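# Methods

## Problem setting

A positional-scanning combinatorial peptide library (PS-CPL) screen probes a
T-cell clone with mixture sublibraries: in each well one peptide position is
fixed to a defined residue and every other position is fully randomised. The
per-well readout (here MIP-1β by ELISA, in ng/mL) gives a
`positions × residues` response landscape r(i, a) describing which residue
the clone's TCR prefers at each position of its peptide–MHC ligand. aplkit
turns such a landscape into a ranked list of candidate super-agonist
(altered peptide ligand, APL) decamers over the full combinatorial universe,
and quantifies the downstream assays used to validate candidates against the
natural tumour epitope (the HLA A2-restricted Melan-A decamer EAAGIGILTV):
dose-response sensitivity, cytotoxicity, priming magnitude, TCR clonotype
overlap, and peptide–MHC structural mimicry.

## Scoring model and exact k-best search

**Model.** After background subtraction (`max(r − background, 0)`, with the
T-cells-alone readout as background; negative values are clipped, not
rejected, since sub-background ELISA values are noise, and a fully zeroed
position is an error since the screen carries no information there) the
landscape is converted to per-position log-probabilities

    w(i, a) = ln( (r(i, a) + ε) / Σ_b (r(i, b) + ε) ),

and a peptide is scored additively, score(s) = Σ_i w(i, s_i). Position
independence is the defining PS-CPL assumption (each well averages over all
other positions), and any strictly monotone per-position transform yields
the same ranking family; the log form makes scores additive, which is what
permits an exact search. The pseudocount defaults to ε = 10⁻³ × max r:
zero-response residues remain finite but pay a large penalty
(≈ ln ε − ln max ≈ −6.9 versus the row's dominant residue). ε is
configurable; ranking differences only appear among residues whose
responses are comparable to ε.

**Search.** Because the score is a sum over independent coordinates, the
top-k of the |A|^L universe is found exactly by best-first search over the
Cartesian product of per-position residue lists sorted by descending weight.
The frontier state is the tuple of per-position indices into those sorted
lists; the start state is the all-argmax peptide, successors increment one
coordinate, and a visited set prevents duplicates, giving
O(k·L·log(k·L)) time and O(k·L) frontier memory — the 20¹⁰ decamer universe
is never materialised. Ties in score are emitted in ascending lexicographic
sequence order; this is deterministic across platforms, and because
per-position residue lists break weight ties by residue letter, every
equal-score predecessor of a state is lexicographically smaller, so the heap
(keyed by (−score, sequence)) pops exact ties in sorted order. A brute-force
enumerator over universes up to 10⁶ sequences serves as the testing oracle;
the suite checks sequence-for-sequence identity, including tie order, on 200
random models.

Candidates are annotated against the index epitope with a per-position
shared-residue mask and Hamming distance, mirroring how APL candidate lists
mark residues retained from the natural antigen.

## Assay quantification

**Dose-response.** Titrations are fit with a four-parameter logistic on the
log₁₀ molar concentration axis,
y = bottom + (top − bottom) / (1 + 10^(hill·(log₁₀EC₅₀ − log₁₀c))),
by bounded least squares (SciPy trust-region reflective). Initialisation:
bottom = min y, top = max y, log₁₀EC₅₀ at the midpoint of the tested
log-concentration range, hill = 1. Bounds: bottom/top within the data range
± 20 %, EC₅₀ within the tested range ± 2 decades, hill in [0.05, 20]. The
4PL (rather than 3PL) is the minimal family covering sigmoid curves of
best fit without fixing the slope. Fits with fewer than four distinct
concentrations, or a dynamic range at or below a configurable floor, raise a
degenerate-fit error rather than returning a meaningless EC₅₀; solutions on
a bound are returned but flagged not-converged. Sensitivity comparisons are
EC₅₀ fold changes, 10^(log₁₀EC₅₀ₐ − log₁₀EC₅₀_b).

**Cytotoxicity.** The flow-based killing assay seeds target cells with and
without effectors and spikes both wells with a fixed CFSE-labelled reference
population before acquisition, so the target:reference event ratio is a
seeding-normalised survival measure:

    % killing = 100 − (exp targets / exp reference) / (con targets / con reference) × 100.

Negative values (target outgrowth over the control) are reported with a
warning, never clipped — losing the sign hides assay failure. Chromium
release uses the standard specific-lysis normalisation
100·(E − S)/(M − S) between spontaneous (targets alone) and maximum
(detergent-lysed) release wells, capped at 100. The two estimators agree to
within sampling error whenever they share a true surviving-target fraction;
the suite checks agreement within 2 percentage points at 10⁴ events.

**Per-cell effector dosing.** When lines of different antigen-specific
purity are compared per tetramer-positive cell, the total cell dose is
ceil(ratio × n_targets / tetramer_fraction); a 1 ns absolute slack in the
ceiling guards against decimal fractions (e.g. 0.008) that are not exactly
representable in binary. **T2 stabilization** is summarised as the MFI ratio
with/without exogenous peptide; > 1 indicates surface-HLA stabilization on
the TAP-deficient line.

**Priming statistics.** Donor × peptide tetramer⁺ percentages are
normalised per donor by min–max (the donor's best peptide maps to 1,
constant rows to 0), which matches a relative-magnitude colour key and is
parameter-free; the combined bar is the mean of normalised donor rows, so
each donor contributes equally regardless of absolute response size
(normalising the mean of raw rows instead would let high-magnitude donors
dominate). Whether to normalise per donor or globally is configurable in
principle; per-donor is the default and the only mode exposed. Paired
two-arm comparisons use the paired one-tailed t-test, t = d̄/(s_d/√n),
df = n − 1, with the hypothesized direction supplied explicitly by the
caller — inferring it from the data post hoc would invalidate the test.
Zero-variance differences are an error (p undefined), not p = 0. CFSE
proliferation subtracts the no-peptide (DMSO) CFSE-low background, clipping
at zero with a below-background warning.

**Clonotype overlap.** A clonotype is (chain, CDR3 amino-acid sequence);
the V gene is reported (usage fractions, clonotype- or read-weighted) but is
not part of identity, matching the convention of counting unique CDR3s.
Overlap reports shared CDR3s per chain, the union of unique clonotypes
across both lines and chains, and per-chain Jaccard indices.

## Structural mimicry

Structures are read from PDB coordinate files (first model; alternate
locations resolved to highest occupancy, ties to altloc A; waters and
hydrogens excluded). **Contacts** count heavy-atom pairs between the peptide
chain and heavy-chain groove residues (default 1–180, the α1/α2 platform
domains) at Euclidean distance strictly below the cutoff. The cutoff
defaults to 4.0 Å — the conventional crystallographic contact threshold —
and is an explicit parameter so counts can be probed at 3.5/4.5 Å.
**Superposition** is least-squares rigid-body (Kabsch via SVD, determinant
correction to exclude reflections); degenerate (collinear) references are
rejected. **Peptide backbone RMSD** superposes the two complexes on groove
Cα atoms and then measures the peptide backbone (N, CA, C, O) without
further fitting, so it quantifies presentation geometry in the groove frame
rather than peptide self-similarity. **Orientation** classifies each peptide
side chain as solvent-exposed or groove-buried from its solvent-accessible
surface area, computed by Shrake–Rupley sphere sampling (golden-spiral
points, default 960; an isolated atom returns exactly 4π(r+probe)²) in the
context of the full complex, relative to Gly-X-Gly tripeptide reference
maxima; the default relative threshold is 0.25. Glycine and residues with
missing side-chain atoms are reported not-classified rather than failing.

## Synthetic data generators

All generators are pure functions of (parameters, seed).

- **CPL screens.** The planted ground truth is an energy matrix over
  10 positions × 20 residues; peptide activation is
  scale · logistic(Σ energy). The default landscape models a highly
  specific, high-avidity clone: one strongly preferred residue per position
  (boost uniform in [3, 4] energy units above an N(0, 0.3) background), rows
  centred to zero mean so random decamers occupy the responsive mid-range of
  the logistic rather than its saturated tails. With 2000 random peptides
  per sublibrary this puts the expected response gap between the preferred
  residue's well and any competitor at ≈ 0.33–0.42 of the activation scale
  against additive well noise of 0.05 · scale (one ELISA readout per well,
  noise at the sublibrary-mean level, not per peptide), i.e. a per-well z of
  ≳ 4.7 — the planted optimum is recoverable as rank 1 from the screen with
  high probability, which is the designed regime of a real PS-CPL screen of
  a specific clone. What passing does not show: recovery for degenerate
  clones whose positions tolerate several residues equally, or epistatic
  (position-coupled) recognition, both outside the PS-CPL additive
  assumption.
- **Titrations** draw 4PL readouts with multiplicative Gaussian noise of a
  given CV; the reference condition is 8 log-spaced concentrations spanning
  10⁻¹²–10⁻⁵ M at 10 % CV.
- **Killing wells** draw surviving experimental targets as
  Binomial(n, 1 − kill fraction) against a control with kill fraction 0 and
  a fixed reference spike (defaults 5 000 targets, 10⁵ reference events,
  the plating scale of the flow assay).
- **Repertoires** plant an exact number of shared CDR3s per chain among
  rejection-sampled globally unique random CDR3s (length 8–20, C…F framing),
  geometric clone sizes, and a TRAV12-2 bias on α chains mirroring the
  germline skew of this specificity.
- **Toy pMHC pairs** build a synthetic two-chain scaffold (60 groove
  pseudo-residues as two helical walls, a 10-residue peptide, N/CA/C/O atoms
  only — a geometric stand-in, not an HLA fold) and return it with a rigidly
  transformed copy whose peptide alone is perturbed by isotropic Gaussian
  noise; groove-frame superposition then recovers the transform exactly and
  the backbone RMSD reflects the planted perturbation (E[RMSD] ≈ √3·σ).

## Numerical choices and limitations

- Exact score ties are detected on float equality; both search paths
  accumulate per-position weights in identical order, so the oracle
  comparison is exact, and output ties break lexicographically.
- Scoring-model rows are renormalised in log space after construction so
  the simplex invariant holds to 1e-9 regardless of row magnitude.
- The acceptance script derives all per-replicate seeds from the single
  `--seed` argument (kept below 2³¹) and regenerates every input at run time.
- Problem sizes used by the test suite and acceptance script — 200 random
  models for the oracle check, 50 simulated screens at 2000
  peptides/sublibrary, 100 titrations, 25 toy structure pairs — were chosen
  to make the Monte-Carlo estimates stable at a few-percent level while the
  whole suite stays interactive-fast.
- Known limitations: no inter-position epistasis in scoring (by design);
  no proteome-wide scanning of candidates against reference databases; no
  mmCIF input; flow-cytometry gating and crystallographic refinement are
  upstream of this package, which consumes event-count tables and refined
  coordinates.
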