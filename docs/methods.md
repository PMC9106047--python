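# Methods

## Overview

`foldadm` predicts coarse protein-folding properties from an amino acid
sequence using statistics of inter-residue Cα–Cα distances accumulated
over a corpus of known structures.  Two analyses share those statistics:

1. **Average distance map (ADM)** — a boolean contact-map-like matrix
   built from sequence alone, whose dense diagonal blocks mark segments
   predicted to compact early in folding.
2. **F-value profile** — a per-residue burial-tendency index obtained by
   Metropolis Monte Carlo sampling of a bead-model denatured ensemble
   under harmonic pair potentials derived from the same statistics.

Supporting analyses identify conserved hydrophobic residues (CHRs) in a
multiple sequence alignment and residue packing by ΔASA on a Cα-sphere
model.

## Distance statistics

For every chain in the corpus and every residue pair i < j, the Euclidean
Cα distance is accumulated under the key (type_i, type_j, M), where the
sequence-separation range M bins k = |i − j| as 1–8 → M = 1, 9–20 → M = 2,
21–30 → M = 3 and decades thereafter.  The table stores the mean d(A, B, M),
the **population** standard deviation (the statistic parameterises a
density model, not an inferential estimate) and the count.  Pairs
involving nonstandard residue letters are excluded; separation counts run
over stored sequence positions, so chain breaks do not interrupt k.

## ADM construction and η-values

A pair (i, j) is plotted when d(type_i, type_j, M) lies **strictly below**
a per-range cutoff.  Cutoffs are calibrated so that the per-range plot
density matches a target: the cutoff is the target-density quantile of
the count-weighted distribution of table means in that range (achievable
only to one table-entry granularity, since a pair type either plots or
does not).  The default target is the true Cα contact density of the
statistics corpus at 8 Å, computed per range; a sequence being predicted
therefore needs no structure of its own.  The `build-stats` command embeds
these densities as `# density M value` comment lines in the stats TSV.

The η-value of a diagonal segment [s, e] is its raw plot density:
plotted pairs within the triangle divided by L(L−1)/2, L = e − s + 1.
Region detection scores **all** O(n²) diagonal segments of length ≥
`min_len` (default 8), keeps those with η ≥ global map density + `margin`
(default 0.05), and selects greedily by descending η with overlap
suppression.  Ties break to the smaller start and then to the longer
(maximal) segment.  Rank 1 is the primary region.  Exhaustive scoring is
affordable because target sequences are at most a few hundred residues.

## Harmonic pair potential

The Boltzmann weight of the pair potential is defined to be the Gaussian
density with the tabulated mean and SD, giving

    v_ij(r) = (r − r̄_ij)² / (2 σ_ij²)    [kT units, kT = 1]

with the additive normalisation constant dropped — the Metropolis rule
consumes only energy differences, so the partition-function term never
appears.  The minimum sits at the average distance r̄, and v(r̄ ± σ) = ½ kT.
σ is floored at 0.5 Å so singleton observations cannot produce singular
potentials.  Pair types absent from the table back off to the
count-weighted range-level pooled mean/SD; a wholly absent range
contributes no energy.

## Bead-model Monte Carlo

One bead per residue, fixed virtual bond b = 3.8 Å, hard-core diameter
4.0 Å between beads at least two apart.  Moves preserve bond lengths
exactly: interior beads rotate about the axis through their two
neighbours (single-bead crankshaft, angle uniform in (−π, π]); terminal
beads are re-placed at a uniform random direction on the bond sphere.
Both proposals are symmetric, so Metropolis acceptance min(1, e^(−ΔE))
satisfies detailed balance; a 3-bead chain reproduces the analytic
distribution p(r) ∝ r·e^(−v(r)) on the hard-core-truncated interval
(χ² goodness of fit in the test suite).

Defaults: 60,000 attempted moves per run, burn-in 10%, one frame recorded
every 10 steps, pairs with |i − j| ≥ 2 governed by the potential, contact
threshold 8.0 Å.  Incremental energies are resynchronised against a full
recomputation every 1,000 steps; the maximum drift is reported and stays
below 10⁻⁸ kT.  All randomness flows from one `numpy` generator seeded by
the caller, so runs are bit-reproducible.

## F-values and peaks

The contact degree C_i = Σ_j g(i, j) of the potential run is standardised
into F(i).  Two modes exist:

- **reference** (default): F(i) = (C_i − mean_r C_i^null) / sd_r C_i^null,
  a per-residue z-score against ≥ 3 replicate zero-potential runs (bonds
  and hard core only).  Replicate potential runs, when supplied, give the
  per-residue intrinsic fluctuation F_sd.
- **internal**: C_i standardised against the distribution of contact
  degrees over residues within the run itself; this mode preserves the
  raw contact-degree ranking.

The per-residue null SD is strongly position-dependent: terminus-adjacent
residues fluctuate least between replicate runs.  Dividing by it
therefore *rescales the ranking*: a residue bonded to a strongly
attracted partner can outrank the partner itself in reference-mode F even
though it gains fewer contacts.  For questions about *which* residues are
most buried (e.g. the planted-attraction recovery test), the internal
mode is the appropriate statistic; the reference mode is the appropriate
measure of *how far* a residue's burial departs from the chain-connectivity
baseline.  Both are exposed; the recovery tests use the internal ranking.

A peak of the F plot is an interior local maximum (leftmost index of a
plateau) whose height exceeds both flanking valleys — the minimum of F
between it and the adjacent candidate maximum, or the terminus — by more
than the intrinsic fluctuation (the maximum local F_sd over that window,
or a scalar fallback of 0.5 when no replicate information exists).
Peak–CHR matching reports every (peak, CHR) pair within ±5 residues,
boundary inclusive.

## CHRs and motifs

The hydrophobic set is {A, F, I, L, M, V, W, Y}.  An ungapped query
position is a CHR when its residue is hydrophobic and the hydrophobic
fraction of non-gap residues in its alignment column is ≥ `min_fraction`
(default 1.0 — hydrophobicity maintained in every homolog; the threshold
is exposed because conservation definitions vary).  Gap columns of the
query are skipped; gaps never enter the denominator.  `motif_pattern`
renders CHR offsets inside a segment as φ/x strings, e.g. φxxxφxxxφ for
the i, i+4, i+8 periodicity of a helix face.

## ΔASA packing

Residues are single Cα-centred spheres of radius 3.0 Å probed at 1.4 Å —
a deliberately coarse residue-level model (an all-atom ASA is out of
scope).  Accessibility is sampled on a deterministic Fibonacci-spiral
lattice (default 256 directions), so results are seed-free and invariant
to rigid motion within ~1%.  ΔASA(i, j) sums, over both partners, the
surface area occluded by the other sphere *alone*; pairs with
ΔASA ≥ 1.0 Å² (configurable) are reported as packed.

## Synthetic study conditions

The fixture generators define the conditions under which the pipeline is
exercised:

- **Planted-proximity corpus** (ADM recovery): 12 chains × 40 residues.
  A 9-residue segment (positions 16–24) carries the planted types (I/L);
  all its range-1 pairs are driven toward 5.5 Å and all other range-1
  pairs toward 12 Å (targets jittered with SD 1.0 Å and clipped to the
  geometrically reachable 0.93·b·k), by constraint projection: repeated
  pair-distance adjustment sweeps with sequential bond re-projection,
  giving bounded runtime.  Backbone realism beyond bond lengths is not
  attempted.  The 9-residue segment keeps every internal pair within
  range 1, so the planted block is homogeneous in M.
- **Planted single-pair 30-mer** (F-value recovery): a poly-G chain with
  W at 6 and F at 24 (separation 18, range 2), planted key r̄ = 5 Å,
  σ = 0.5 Å; every other occurring key gets an explicit coil-like entry
  with σ = 50 Å, i.e. effectively zero force, so the range-level backoff
  cannot leak the planted parameters to other pairs.  The partners sit
  five residues in from each terminus: far enough from the ends to remain
  long-range, close enough that the competing mid-chain baseline does not
  swamp the signal.  Across repeated seeds the partner pair's sampled
  contact frequency is ≈ 1 versus a null of ≈ 10⁻³–10⁻², and the partners
  carry the two largest contact degrees in roughly nine of ten runs —
  occasionally a bonded neighbour, dragged into the same contact shell,
  overtakes one partner within a single 60,000-step run.
- **Toy MSA**: gapless alignment mutating non-conserved positions to
  non-hydrophobic letters at a given rate, preserving the query residue
  at planted conserved positions.

What passing on these fixtures shows: the statistics, calibration,
region detection, sampling and standardisation machinery recover signals
they were told the ground truth of.  What it does not show: performance
on real proteins, where the distance statistics mix secondary-structure
preferences, the denatured state is not a Gaussian-pair polymer, and
alignments contain gaps and phylogenetic correlation.

## Numerical choices and degenerate inputs

- Strict inequality (mean < cutoff) in ADM plotting; calibration nudges
  the quantile mean by one ULP so the achieved fraction is ≥ target.
- A range requested but absent from the stats table inherits the nearest
  lower range's cutoff (with a warning).
- η is undefined for segments shorter than 2 residues (error).
- Zero null variance in reference-mode F raises an error asking for more
  or longer reference runs rather than returning infinities.
- Self-avoiding chain growth retries per bead (60 attempts) and restarts
  the whole chain (200 attempts) before failing.
- Crankshaft axes shorter than 10⁻⁹ Å fall back to a random axis.
- Simulation sizes in the test-suite recovery runs follow the study
  conditions above (60,000-step runs, 10 seeds, 20 corpora); the 3-bead
  calibration check uses 10⁵ steps with every-20-step recording to keep
  frames approximately independent.

## Known limitations

- The ADM calibration matches *corpus-level* contact densities; per-range
  densities of any single query protein will differ.
- Reference-mode F-values are sensitive to the null-SD profile at chain
  termini (see above); profiles from short chains (< ~20 residues) should
  be read with care.
- The move set is local (single-bead); relaxation of long-range loop
  modes is slow, so contact frequencies from a single 60,000-step run
  carry appreciable run-to-run variance — hence replicate runs for the
  intrinsic fluctuation.
- The Cα-sphere ΔASA model ignores side-chain geometry entirely; it
  captures pair adjacency, not true packing surface.
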