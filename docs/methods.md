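# Methods

This note documents the models, parameter choices and numerical
decisions behind `genofp`, and what the synthetic-data experiments do
and do not demonstrate.

## Data model

A genotype database is an M × N table of minor-allele counts in
{0, 1, 2}, wire-encoded as the 2-bit patterns '00', '01', '10'. The
pattern '11' (value 3) is not a genotype and may exist only transiently
inside mark writing. The row identifier string is the primary key: every
keyed selection concatenates it, so selection is invariant to row
reordering but *not* to identifier renaming — a renamed or subsetted
copy is outside the threat model here (subset/superset attacks are
deliberately out of scope).

Mendelian consistency of a mother–father–child trio at one locus is
checked strictly: the child's count must decompose as one transmissible
allele per parent (a parent with count 0/1/2 transmits 0 / {0,1} / 1
minor alleles). De-novo mutation is counted as a violation; no tolerance
knob is exposed.

## Keyed selection

The five pseudorandom quantities used by insertion and extraction are
domain-separated HMAC-SHA256 channels over UTF-8 tokens joined with a
literal `|` byte: `U_c(K, t1, t2, ...) = HMAC(K, "U<c>|t1|t2|...")`,
read as a big-endian integer. The fingerprint index is 0-based,
l = U4 mod L. Any keyed, deterministic cryptographic generator would do;
HMAC is chosen because it is portable and bit-exactly testable. The
fingerprint string is MD5(K | n) giving L = 128 bits; L is exposed for
experimentation. The fingerprint machinery takes no RNG seed at all:
the key determines everything, which is what makes blind extraction
possible.

## Mark writing and the '11' rule

Writing mark m into bit position t of a cell can produce '11'. The
implementation then clears the *other* bit (t = 1: '11'→'01'; t = 2:
'11'→'10'). This keeps every released value a valid genotype — an
invalid value would advertise the mark's location — while the bit that
extraction reads still equals m exactly. Consequence: a mark can change
a cell by up to two units (e.g. 2→1 via '11'), and roughly half of all
marks leave the cell unchanged (the mark equals the resident bit).

## Vote multiplicity and what it implies for flip robustness

With row density γ_r and within-row density γ_l, the expected number of
marked cells is M·N / (⌊1/γ_r⌋·⌊1/γ_l⌋), spread uniformly over the 128
fingerprint indices. At M × N = 1500 × 156 and γ_r = γ_l = 0.09 this is
≈ 1 930 marks, i.e. ≈ 15 votes per index. A random flip of 15% of all
cells corrupts each vote with probability ≈ 0.08 (a flipped cell changes
the read bit about half the time), so the probability that a τ = 0.7
majority is lost at any index is ~10⁻³ and the measured mean Percmp is
1–3%. This is a structural consequence of marking γ_l of the cells in
every selected row: schemes that mark a single cell per selected row
have ≈ 1 vote per index and lose ~35% of bits under the same attack
simply because a third of the indices receive no vote at all. The test
suite asserts the published single-mark-style operating point and
therefore carries one intentionally failing check; the measured value
for this scheme is the honest output of `scripts/acceptance.py` (key
`t2`).

Undetermined template symbols count as compromised bits by default
(the owner cannot confirm them); `--undet-policy ignore` restricts the
count to determined-but-wrong bits.

## Row-wise mitigation

Mendel repair visits every trio locus that violates inheritance *and*
contains at least one mark. Only non-fingerprinted members may change;
candidate reassignments are searched child-first (child, mother,
father; single-member edits before pairs), minimizing total absolute
change with ties broken toward lower genotype values. Loci with all
three members marked are unrepairable and are skipped (counted in the
report) — these are exactly the residual violations a row attacker can
still find, which is why the count matters.

Similarity restoration treats the public kinship model S as
inner-product similarities of parent–child genotype vectors. The
integer program that would exactly restore all similarities is replaced
by the greedy unit-move heuristic: each '0-0-0'→'1-0-1' (mother–child)
or '0-0-0'→'0-1-1' (father–child) conversion of a fully unmarked trio
tuple moves one similarity by exactly +1 and provably leaves the other
first-degree pair of the trio untouched; the reverse moves subtract 1.
The summed absolute gap Σ|s − s̃̃| is therefore non-increasing and
reaches 0 whenever enough eligible tuples exist ('0-0-0' is the most
common tuple in practice; exhaustion is logged).

## Column-wise mitigation and the Sinkhorn solver

For each locus p the empirical marginal after fingerprinting is
transported onto the public marginal Pr(C_p) = J_{p,q}·1ᵀ (any partner
q gives the same marginal; the loader checks this to 10⁻⁶). The plan
solves min ⟨G, Θ⟩ − H(G)/λ over the transport polytope.

* **Cost** Θ(a,b) = |a−b|: zero diagonal, positive off-diagonal, and a
  0↔2 double move costs twice a single move — biologically a two-allele
  rewrite. Configurable.
* **λ = 50** by default: effectively the near-LP regime, producing the
  most heterogeneous plan and hence the fewest cell edits. Smaller λ
  approaches the independent coupling (many edits). Exposed per call.
* **Solver**: alternating scaling on exp(−λΘ) in the plain domain
  (fast), with an automatic log-domain retry if scaling factors
  overflow. Tolerance 10⁻⁹ on both marginal residuals, 10 000 sweeps
  maximum. Scaling converges only linearly and its rate degrades with
  λ·max(Θ); when it stalls above tolerance (observed down at residuals
  ~10⁻⁵–10⁻³ for near-diagonal instances) the near-feasible plan is
  projected onto the polytope by marginal rounding — rows then columns
  scaled down to their targets, leftover mass spread as a rank-one
  correction — which is exact on the marginals and perturbs the plan by
  at most the stalled residual. Plans whose residual exceeds 0.02 raise
  instead. Empty categories are dropped before scaling and restored as
  zero rows/columns.
* **Execution**: each off-diagonal entry G(a,b) becomes
  round(G(a,b)·M) cell edits (half-away-from-zero), drawn uniformly
  without replacement from the non-fingerprinted cells of the column
  holding value a; exhaustion is logged.

Because edits are drawn uniformly per column, column mitigation restores
*marginals* (per-column total-variation distance to the target is
non-increasing — asserted in tests) but cannot rebuild *joint*
structure: random edits shrink covariance toward independence. The
guarantee for pairwise LD is therefore closeness, not improvement: on
the synthetic populations the robust copy keeps locus-pair Pearson
correlations within a small fraction of the J-implied values (tested at
mean gap < 20% of the mean reference correlation at γ = 0.15). A
selection rule that conditions on neighbouring columns could do better
and is a known limitation, not an implemented feature.

## Attacks

The attacker holds S, J and the pedigree but no mask, and spends at most
a cell-change budget. The row attack first repairs every Mendel
violation by flipping one uniformly chosen member (among those
admitting a single-value fix) to its nearest consistent value, then
ranks parent–child pairs by |S′−S| and applies the same tuple moves as
the defense — in the direction of S — until each pair is within 1
(inner-product units) or the budget runs out. The column attack ranks
loci by total-variation discrepancy and transports marginals above a
0.005 TV threshold using the same Sinkhorn machinery, on uniformly
random cells since marks are indistinguishable. The combined attack is
row then column under one budget. The flip attack changes exactly
round(fraction·M·N) distinct cells to a uniformly random *different*
valid value — a pure bit complement could produce the impossible '11'
pattern, which a rational attacker avoids.

## Synthetic populations

The generator emulates a family-based genotyping panel: founder
haplotypes follow a first-order Markov chain along the genome with
stationary per-locus minor-allele frequency `maf` (default 0.25, in
(0, 0.5]) and adjacent-locus allele correlation `ld_r` (default 0.4 in
the experiments); a founder genotype is the sum of two independent
haplotypes; each child locus receives one uniformly chosen allele from
each parent's two haplotypes, independently per locus, flipped with
probability `mutation_rate` (default 0, so trios are exactly Mendel
consistent). Ground-truth knowledge is measured from the generated
matrix: S as all parent–child inner products, J as empirical 3 × 3
joints of adjacent locus pairs (optionally extra random pairs).

What this emulates: realistic allele-frequency spectra at one scale,
first-degree kinship correlation, and tunable adjacent-pair LD — enough
to give every attack and defense stage non-trivial signal. What it does
not: long-range LD blocks, recombination/IBD segments, population
stratification, genotyping error and missingness. Passing tests
demonstrate the scheme's mechanics and the attack/defense orderings on
this model, not performance on any particular real panel.

Experiment scales are chosen to mirror the two reference panel sizes:
1500 × 156 with 150 trios for the flip-robustness measurement (20
seeds) and 8000 × 234 with 1333 trios for the robust-scheme bound
(γ ∈ {0.06, 0.08, 0.1}, attack budget 25% of cells); smaller
populations (hundreds of rows, tens of loci) are used in the property
tests to keep the suite fast.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| γ_r, γ_l | — (required) | row / within-row mark densities in (0,1); realized rates are 1/⌊1/γ⌋ |
| L | 128 | fingerprint length in bits (MD5) |
| τ | 0.7 | extraction confidence threshold in (0.5, 1] |
| λ | 50 | inverse entropy regularization of transport plans |
| tv_threshold | 0.005 | column attack ignores marginals closer than this TV |
| sim_tol | 1 | row attack stops a pair within this inner-product gap |
| undet policy | mismatch | undetermined bits count as compromised |

## Known limitations

* Detection assumes the leaked copy keeps the row identifiers and locus
  labels of the shared copy; subset, superset and collusion attacks are
  out of scope.
* Mendel repair cannot fix loci where all three trio members are
  marked; these are skipped and reported, and remain attacker-visible.
* Column mitigation preserves pairwise correlation only approximately
  (see above).
* The flip-robustness operating point of single-mark-per-row schemes is
  not reproduced by this scheme's dense marking; see the vote
  multiplicity section.
* The GWAS case/control split is an unstratified random 50/50 partition;
  family structure makes the two groups non-independent, which is
  acceptable for consistency comparisons (the same split is reused on
  both databases) but not for inference.
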