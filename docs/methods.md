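# Methods

## Ensemble and span constraint

A secondary structure is a well-nested set of canonical base pairs
({AU, UA, CG, GC, GU, UG}; any pairing involving N is forbidden).  A pair of
residues `(k, l)` must satisfy `5 ≤ l − k + 1 ≤ W`: the lower bound is the
minimum hairpin of 3 unpaired bases, the upper bound is the maximal span
`W`.  The ensemble is the set of *globally consistent* structures of the
whole sequence under this constraint — not an average over sliding windows.
Lonely (isolated) pairs are allowed.  Positions are 1-based; dynamic
programming uses gap coordinates `0..N`, and an outermost pair written as a
gap pair `(i, j)` pairs residues `(i+1, j)`, so the set of potential
outermost pairs is `P = {(i,j) : (x_{i+1}, x_j) canonical, 5 ≤ j−i ≤ W}`.

## Energy model

Loop free energies (kcal/mol at T = 310.15 K, R = 1.9872e-3 kcal/mol/K) are
a deliberately compact nearest-neighbour set:

* stacking energies for all 36 ordered pair combinations (Turner-like
  default values, symmetric under reversing the helix);
* hairpin/bulge/internal-loop initiation by loop size, with
  Jacobson–Stockmayer extrapolation `ΔG(n) = ΔG(n_max) + c·ln(n/n_max)`
  beyond the table (`c` = 1.08 kcal/mol in the bundled file);
* internal/bulge loops larger than 30 bases are excluded from the ensemble
  (weight 0) — this cap is part of the model definition and is applied
  identically by the enumeration oracle, so engine-oracle comparisons are
  exact, not approximate;
* affine multiloops `a + b·(inner branches) + c·(unpaired)`, defaults
  (3.4, 0.4, 0.0); the closing pair contributes `a` only;
* exterior loops are unweighted by default (`t(Outer→Outer) = 1`); the
  optional `dangle_mode="simplified"` charges a terminal-AU-style penalty
  (0.5 kcal/mol) to non-CG exterior closing pairs, off by default.

Boltzmann weights are `exp(−ΔG/RT)` with negative ΔG stabilising.  Full
Turner-2004 fidelity (coaxial stacks, special hairpins, mismatch tables) is
intentionally out of scope: every consumer of the engine, including the
oracle and all tests, shares this model, so algorithmic correctness is
decoupled from parameter richness, and the parameter file format
(`STACK`/`HAIRPIN`/`BULGE`/`INTERNAL`/`MULTI` TSV sections) lets users
substitute richer tables of the same shape.

## Grammar

The engine uses an unambiguous Rfold-style decomposition with states
Outer, Stem, StemEnd, Multi, MultiBif, Multi1, Multi2 (MultiBif is the
bifurcation point).  `Stem(i,j)` closes pair `(i+1, j)` and either stacks
directly (`Stem → Stem`) or opens a loop (`Stem → StemEnd`); `StemEnd`
branches into hairpin, internal/bulge + inner Stem, or a multiloop whose
contents are parsed with leading-unpaired stripping (Multi), a unique last
split (MultiBif = Multi1 · Multi2), first-branch-flush left parts (Multi1)
and single-branch-plus-trailing-unpaired right parts (Multi2).  Every
structure has exactly one derivation; this is not assumed but enforced
empirically — with all energies zero the partition function must equal the
independent census of structures, checked over all `W` on random sequences.

Unambiguity matters beyond `Z`: the per-position structural profile is read
off transition probabilities (`β_state · t · α_state' / Z`), attributing
each unpaired residue to the unique loop that emits it (hairpin emission,
internal-loop side ranges, the two single-residue multiloop steps, or the
exterior step).  Profile rows must sum to 1 at every position, which the
long-sequence acceptance check verifies to 1e-9 at N = 100,000.

Inside values for all states are banded (span ≤ W) and bounded, so they are
stored directly in the log domain.  All sums of Boltzmann terms are
log-sum-exp; zero weight is −inf.  The banded kernels are numba-compiled;
inside + outside + ratio construction is `O(N·W²)` time and `O(N·W)`
memory (about 3 minutes and ~2 GB at N = 100,000, W = 50 on one CPU).

## Ratio dynamic programming

The exterior variables `α_Outer(j)` (prefix partition values) and
`β_Outer(j)` (suffix) grow exponentially with N.  The engine never stores
them; it computes their fold changes directly:

    Δα(j−1) = 1 + Σ_{p} [Π_{h=p}^{j−2} Δα(h)]⁻¹ · t_ext · e^{α_Stem(p,j)}

over `p ≥ j − W`, i.e. each fold change follows from the previous `W` fold
changes and the banded Stem blocks — the recursion for Δβ is the mirror
image.  Both are bounded: `1 ≤ Δα(h) ≤ 1 + W·max-block-weight`, whatever N.

All probabilities come from the ratio `r(i,j) = Z/(α_Outer(i)·β_Outer(j))`.
Anchoring at a position i′ partitions the ensemble by the status of residue
i′+1 — exterior-unpaired (the degenerate step `(i′, i′+1)`) or covered by an
outermost pair `(p, q)` with `p ≤ i′ < q` — giving

    ρ(i) = Z/(α_i·β_i) = Δβ(i)⁻¹ + Σ_{(p,q)} (α_p/α_i)·u(p,q)·(β_q/β_i),

where `u(p,q) = t_ext·exp(α_Stem(p,q))` and the α/β ratios are local Δ
products; then `log r(i,j) = log ρ(i) + Σ_{h=i}^{j−1} log Δβ(h)`.  The
outside pass runs on probability scale (`β_state/Z`): the exterior context
enters Stem cells as `t_ext / r(i,j)` and everything else propagates within
bands, so no intermediate ever exceeds the scale of a window.  Anchor
independence of the decomposition and agreement of `r`, `β/Z` and all
probabilities with a raw log-domain reference fold are tested on short
sequences to 1e-9; the double-precision engine matches exhaustive
enumeration to ~1e-13 in practice.

## Divide / Connect

For a segment with gap range `[s, e]`, `α_Outer(k)` for `k > s` is linear
in the boundary vector `α_Outer(s−h)`, `h = 0..min(W−1, s)` (the span bound
means gap `s−W` is never referenced, so the chain count is W, one fewer
than a naive reading suggests).  Each Divide job computes the coefficient
chains `α^h_k` with its own banded inside pass over the segment plus W
residues of context per side — `O((N/K)·W²)` per job, independent of all
other jobs — and persists the scale-free ratios `dα^h_k = α^h_k/α^0_k`
together with the chain-0 fold changes.  `dα^h_k = 0` (log −inf) is normal
(no outermost pair leaves gap `s−h`, e.g. in unpairable stretches).

Connect sweeps segments left-to-right carrying
`A_h = log α(s−h)/α(s)` (products of already-merged fold changes) and emits

    log Δα(k−1) = F(k) − F(k−1) + log δ⁰(k),
    F(k) = logsumexp_h (A_h + log dα^h_k),

and mirrored right-to-left for Δβ.  The low-disk variant persists the
d-chain columns only for the W+1 boundary gaps per segment (disk
`O(N + K·W²)`): a first sweep over the boundary blocks recovers every
segment's `A_h`/`B_h` exactly, after which each segment's second DP round
regenerates its interior chains in memory — twice the DP time and
byte-identical output, verified by string equality of the serialized
databases.  K-invariance holds to ~1e-12 at N = 3,000, W = 100 (acceptance
bound 1e-10); all TSV serializations print floats with 17 significant
digits, which round-trips float64 exactly (bit-stable re-runs, resumable
jobs).

## Features

* **Base-pair probabilities** `p(i,j) = exp(α_Stem + log β_Stem/Z)`, banded.
* **Stem probability / accessibility** by row/column sums of the band.
* **Structural profile** from transition probabilities as above; loop-type
  attribution is strictly by paired/unpaired status (a mismatch base
  adjacent to a closing pair counts as loop, not stem).
* **γ-centroid** for γ ≤ 1: all pairs with `p > 1/(γ+1)`.  The threshold is
  strict, so probability-exactly-1/2 ties are excluded; since two
  incompatible pairs cannot both exceed 1/2, the result is conflict-free
  and well-nested by construction (validated anyway).  γ > 1 would require
  a DP assembly of compatible pairs and is unsupported.
* **Window averages**: non-overlapping (⌊N/L⌋ windows, trailing partial
  window dropped, never padded) or sliding (N−L+1 windows).
* **Splice deltas** `Δq_stem(i) = p_stem,mRNA(i) − p_stem,pre-mRNA(map(i))`
  at exonic sites (exon tables are 1-based inclusive), with per-junction
  median and median absolute deviation over a 200-nt window and optional
  32-nt sliding smoothing applied separately upstream/downstream of the
  junction so windows never straddle it.

## k-mer regression

Targets are mean stem probabilities of non-overlapping 32-nt windows
(chosen because windowed means are near-normal, unlike the bimodal
single-base probabilities); features are `(1/32, #AAAA/32 … #UUUU/32)`
(257 dimensions; the 256 counts sum to 29/32; windows containing N are
dropped).  The ridge objective `½Σ(y−wᵀx)² + (λ/2)wᵀw` penalises every
coordinate, intercept included, and is solved in closed form
(`λ = 0` falls back to the minimum-norm pseudoinverse solution, since the
intercept equals 29⁻¹… times the count sum exactly).  λ defaults to 1.0 on
this feature scale and is exposed everywhere; feature standardisation is
not applied.

A caveat discovered while validating recovery: 4-mer counts of literal
32-mers carry overlap-induced near-collinearity (prefix/suffix parity
directions with smallest singular values ≈ 0.4 at n = 5,000), so individual
weights along those directions are weakly determined at noise 0.01 (errors
up to ~0.13).  The planted-weight recovery experiment therefore samples
per-window compositions from a sparse Dirichlet(0.1)-multinomial (29 counts
— compositional diversity of the kind real genomic windows show) and plants
a truth orthogonal to the single exact collinearity; recovery of all 256
4-mer weights is then < 0.05.  Residualization behaviour (zero training
residual mean, decorrelation of adjacent windows) is tested on
sequence-derived designs, where it does not depend on weight
identifiability.

## Statistics

MCC uses the standard `(TP·TN − FP·FN)/√(margins)`; AUC is the rank-sum
(ties half-counted) formulation.  Both Wilcoxon statistics use mid-ranks,
the tie-corrected variance, no continuity correction, and are reported as
Z (one-sided p-values underflow at genome-scale n; Bonferroni correction is
a threshold transform on Z).  The rank-sum path operates on binned
(value, count) input — raw samples are binned losslessly first — so
n ≈ 10⁷ needs only O(#bins) memory, and binned/raw paths agree to 1e-12 by
construction.  Signed-rank drops zero differences.  Cross-checks against an
independent reference implementation (asymptotic, no continuity) agree to
1e-6 on random data; null calibration at n = 10⁴ gives |Z| < 3 in ≥ 99/100
runs.  Positional profiles average aligned per-position series ignoring
missing positions; log-relative profiles divide by the mean over ±300 nt of
the anchor; density log-ratios use histogram densities with an add-half
pseudocount in empty bins.

## Synthetic data

The generators define the test conditions: i.i.d. random sequences with a
given GC fraction (0.5 unless a check is specifically about composition),
perfect Watson–Crick hairpins with random arms, and a toy three-exon gene
whose introns begin with the reverse complement of the preceding exon's
last 10 bases, so splicing removes pairing partners and depresses
`Δq_stem` near junctions.  What they do not emulate: real base
composition heterogeneity, repeats, genuine splice-site motifs, or any
experimentally measured structure — so passing tests demonstrate
algorithmic exactness of the ensemble computation under the stated model,
not predictive accuracy on real transcripts.

The enumeration oracle lists every span-constrained structure (guarded to
N ≤ 25), scores each by loop decomposition, and derives Z, `p(i,j)`,
`p_stem`, loop profiles and outermost-pair frequencies by direct summation,
with loop types classified geometrically per structure.  Its only shared
code with the engine is the energy model; a second, list-free recursive
census cross-checks the enumeration itself.

## Numerical choices and sizes

* log-sum-exp everywhere; cross-check tolerance 1e-9 (log domain),
  achieved with ~1e-12 margin in double precision.
* Acceptance-scale problem sizes, chosen as representative study
  conditions: 200 oracle sequences with N ∈ [8, 22] over every W ∈ [4, N];
  K-invariance at N = 3,000, W = 100, K ∈ {1,2,3,5,8}; stability at
  N = 100,000, W = 50; regression recovery at 5,000 windows; calibration
  over 100 runs of n = 10⁴.

## Known limitations

* Simplified energy set (no coaxial stacking, no sequence-dependent
  internal-loop tables, no dangles by default); absolute probabilities will
  differ from richer parameterisations, though the algorithmic guarantees
  do not.
* Locality of mid-sequence probabilities is soft: with 5W of flanking
  context the max |Δp_stem| over a 200-nt motif is typically a few 1e-4,
  but the per-context distribution is heavy-tailed (occasionally a few
  1e-3 at W = 50) because truncation can sit inside an extended helical
  region.  Probabilities near sequence ends (within ~W) genuinely differ
  from mid-sequence values; this is a property of the model, not an error.
* γ-centroid assembly for γ > 1, MEA decoding, stochastic sampling and
  pseudoknots are out of scope.
* Divide jobs are process-level; multi-host scheduling is left to the
  caller (the file contract is the interface).
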