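# Methods

## Model

`pairdca` fits a global pairwise (Potts) model to a concatenated paired
alignment of two interacting proteins and uses it to separate direct from
transitive residue covariation.

**Alphabet.** 21 states: the 20 standard amino acids plus the gap, which
is a full categorical state (code 0).  Nonstandard letters
(`X B Z U O J *`) are collapsed onto the gap state with a logged warning,
keeping the model closed; `.` is read as an alternative gap glyph.

**Pairing and concatenation.** Records are paired by identical FASTA
identifier — unpaired identifiers are reported and dropped, never
guessed.  Each pair is joined `seq_A + spacer + seq_B` with a spacer of
`spacer_len` identical residues (default 20 alanines).  The spacer exists
to mark the protein boundary through the external alignment; it carries
no signal.  Alignment itself is delegated to an external aligner (MAFFT
in practice): the package writes the concatenated FASTA and re-ingests
the aligned result.  Pre-aligned inputs (such as the synthetic
generator's equal-length records) skip that step.

**Insert columns.** A column is an insert column iff the designated
reference sequence (selectable by id; the first record by default)
carries a gap there.  Removing them makes L equal the reference's
ungapped concatenated length, so alignment columns map 1:1 onto reference
residue numbers — the position map then tags each column `A`, `SPACER`
or `B` with a 1-based residue number inside its segment.

**Reweighting.** Sequence `m` gets weight
`w_m = 1 / |{m' : identity(m, m') ≥ 1 − θ}|` (self included, gap counted
as an ordinary state), with `θ = 0.2`; `M_eff = Σ w_m`.  This is the
standard defence against phylogenetic redundancy: k exact duplicates
carry the weight of one sequence, so all downstream statistics are
exactly invariant under duplication.

**Frequencies.** Weighted counts with a uniform pseudocount of total mass
`λ` (default `λ = M_eff`, i.e. a 50/50 data/pseudocount mix — the
customary mean-field DCA default, exposed as `lambda_ratio`):

    f_i(a)    = (λ/q   + Σ_m w_m [A_mi = a]) / (λ + M_eff)
    f_ij(a,b) = (λ/q²  + Σ_m w_m [A_mi = a][A_mj = b]) / (λ + M_eff)

Diagonal blocks keep their pseudocount on the `a = b` cells only, so pair
tables marginalise exactly to the single-column frequencies.  That
exactness is why MI is computed through the entropy identity
`MI_ij = H_i + H_j − H_ij` (one log pass instead of three large
temporaries); the unit tests pin it against the literal double sum at
1e−12.

**Couplings.** The connected-correlation matrix
`C_(i,a),(j,b) = f_ij(a,b) − f_i(a) f_j(b)` is built over the reduced
20-state alphabet with the gap as gauge reference.  With a positive
pseudocount C is symmetric positive definite, so the inverse is computed
by Cholesky factorisation (LAPACK `potrf`/`potri`); a failed
factorisation raises an error telling the user to increase the
pseudocount.  Couplings are `e_ij(a,b) = −(C⁻¹)` blocks, `i ≠ j`.

**Direct information.** Per pair, the two-site direct distribution
`P_ij(a,b) ∝ exp(e_ij(a,b)) ĥ_i(a) ĥ_j(b)` is fitted by a damped
fixed-point iteration on the auxiliary fields (damping 0.1, deterministic
initialisation at `f_i`, `f_j`), run vectorised over all pairs at once;
convergence is declared when the worst marginal mismatch drops below
1e−4 (cap 500 iterations; exceeding it raises an error naming a pair).
`DI_ij` is the MI of `P_ij` against `f_i ⊗ f_j`.  Random alignments
converge in a handful of iterations; strongly coupled planted pairs in a
few dozen.

**Pair table.** All `N(N−1)/2` pairs of the N analysed columns, four
columns `(i, j, MI, DI)`, in nats.  Spacer columns are excluded *before*
N is counted (they are artificial, zero-variance, and would only add
noise rows); the emitted `i, j` stay in the original concatenated
coordinate system so the position map applies unchanged.  Fully conserved
biological columns are retained — pseudocounts keep every quantity
finite and they simply score MI ≈ 0.

## Post-processing

The proximity filter removes rows with `|i − j| ≤ min_sep` (boundary
included; default 5) — close residue numbers covary for local structural
reasons rather than interaction.  It runs in concatenated coordinates
before any translation, so with `spacer_len ≥ min_sep` it provably never
touches an inter-protein pair.  The strict-inequality reading of
"within five residues" would keep `|i − j| = 5` rows; the inclusive
convention was chosen and is exposed via `--min-sep`.

Anchor ranking selects all scored partners of one residue (an anchor
implicated by genetics) within an inclusive residue range of the partner
protein (domain boundaries are user configuration, not hard-coded), sorts
descending by MI or DI, and breaks ties by ascending partner residue
number so rankings are deterministic and input-order invariant.

## Structure distances

Ranked pairs are validated on any PDB complex model.  The default
distance is the minimum over all heavy-atom pairs: reported side-chain
contacts of 2–3 Å are impossible to see in Cα–Cα mode, which is kept for
comparison only.  When one partner is a homodimer its segment maps to
several chains and the minimum over chains is reported, since a docking
model does not say which protomer an interaction uses.  Residues missing
from the model yield a missing-distance marker, not an error.  Parsing is
strict (malformed records are reported with their line number); hydrogens
and HETATM records are ignored.

## Synthetic data and what it does (not) show

The generator emulates the study conditions — a few hundred to a few
thousand species, two proteins of modest length, a handful of genuinely
co-evolving inter-protein positions:

* **Planted pairs** are drawn iid per species from explicit q×q joint
  tables; the default "permutation-like" joint maps 8 amino-acid states
  one-to-one with 85% of the mass (true MI 1.435 nats, comfortably above
  1 nat).  Planted pairs form a matching, so sampling is exact and, for
  each isolated pair, the generator's own direct model *is* the joint —
  true DI equals true MI.
* **Background columns** are iid from per-column profiles drawn once from
  a symmetric Dirichlet (concentration 1) at spec construction and stored
  in the spec for reproducibility.
* **Gaps** are iid per cell at `gap_rate` (default 0.05), independent of
  the underlying state.  Consequently the emitted MI of a planted pair is
  exactly `(1 − g)² ×` the joint's MI — the closed-form oracle the
  estimator-consistency checks compare against.
* **Redundancy** appends mutated clones per record (default off;
  invariance checks use 4 clones at substitution rate 0.02).

Defaults: `len_a = 30`, `len_b = 40`, `M = 2000`, 5 planted pairs.  These
sizes make a full pipeline run take seconds while keeping the planted
signal at a realistic strength relative to finite-sample noise; the
consistency checks deepen to `M = 5000`.

What passing these tests does *not* show: real alignments have
phylogenetic correlation structure (not iid clones), alignment errors,
column-dependent gap patterns, and many weak couplings rather than a few
strong isolated ones.  The synthetic results validate the estimator and
the plumbing, not biological effect sizes.

## Numerical choices and edge cases

* MI with `λ = 0` skips zero cells (0·log 0 = 0); a tiny additive guard
  (1e−100) protects the DI logarithm, mirroring common practice.
* Weight comparisons use exact integer match counts divided in float64,
  so the vectorised one-hot product agrees with the O(M²L) definition
  bit-for-bit.
* Duplicate-sequence invariance holds to ~1e−13 (BLAS summation-order
  effects only).
* Degenerate inputs fail loudly: all-gap reference rows, empty
  intersections of paired FASTA ids, duplicated ids, singular correlation
  matrices, unconverged field fits.
* With `λ = 0` the MI estimator is used for oracle comparisons; the large
  default pseudocount deliberately biases MI towards zero and is meant
  for stabilising the coupling inversion, not for unbiased MI estimation.

## Known limitations

* Mean-field inversion overestimates strong couplings (planted DI comes
  out above the true value); rankings are unaffected, absolute DI values
  should not be interpreted as information content.
* No average-product correction, pseudolikelihood variant, or
  significance calibration of MI/DI — ranking is the interface, as in
  the motivating analysis.
* The paired-MSA stage trusts the user's curation: ortholog
  identification and paralog disambiguation are out of scope.
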