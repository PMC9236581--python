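# genofp — robust fingerprinting of SNP genotype databases

`genofp` lets the owner of a SNP genotype database (individuals × loci,
each entry the minor-allele count 0/1/2) share a copy with each service
provider (SP) that carries a hidden, recipient-specific fingerprint. If
a copy leaks, blind extraction from the leaked table identifies which
recipient it was. Because genomic data is highly structured, a malicious
recipient can try to erase the marks by *restoring* that structure —
Mendelian trio consistency, kinship similarities and linkage
disequilibrium (LD); `genofp` implements those correlation attacks and
the mitigation post-processing that defeats them, together with the
robustness and utility metrics to measure both sides.

## The scheme

**Insertion.** For SP *n*, the owner derives a fingerprint
f = MD5(K | n) ∈ {0,1}¹²⁸ from her secret key K. A keyed pseudorandom
generator U (HMAC-SHA256 channels U1…U5) selects rows at density γ_r
(row i is marked iff U1(K|i) mod ⌊1/γ_r⌋ = 0), cells within a selected
row at density γ_l, and for each selected cell: a mask bit
x = U3 mod 2, a fingerprint index l = U4 mod L, and a bit position
t = (U5 mod 2)+1 in the 2-bit genotype encoding ('00', '01', '10').
The *t*-th-to-last bit is overwritten with the mark m = x ⊕ f_l. If
this would produce the invalid pattern '11', the other bit is cleared,
keeping every released value in {0,1,2} while preserving the bit that
extraction reads.

**Extraction.** From any same-schema copy, the owner re-derives the
marked positions (they depend only on K and the row/locus labels), reads
each mark back, recovers one vote f_l = m ⊕ x per marked cell, and
thresholds per-index votes at confidence τ (default 0.7):
f(l) = 1 iff c₁(l)/(c₀(l)+c₁(l)) ≥ τ, 0 symmetrically, otherwise
undetermined. The robustness metric Percmp is the fraction of the 128
positions not recovered correctly; utility metrics are cell accuracy
(Acc, with Perchg = 1 − Acc) and the consistency of GWAS association:
per-locus odds-ratio P-values

    OR = C₀(S₁+S₂) / (S₀(C₁+C₂)),  z = ln(OR)/StdErr(ln OR),
    p = Ψ(−|z|) + 1 − Ψ(|z|)

under a random case/control split, and the overlap of the top-50
lowest-p loci before and after a transformation.

**Attacks.** `flip` replaces random cells with another valid value;
`Atk_row(S)` repairs Mendel-violating trio loci and pushes empirical
parent–child inner-product similarities toward the public values S;
`Atk_col(J)` pushes each column's empirical marginal toward the public
marginal implied by pairwise joint distributions J.

**Mitigation (the robust scheme).** After insertion the owner, who knows
the mask, (1) repairs mark-induced Mendel violations by editing only
non-fingerprinted trio members, (2) restores parent–child similarities
with '0-0-0' ↔ '1-0-1'/'0-1-1' tuple moves on unmarked tuples, and
(3) moves each column's marginal back to the J-implied one using an
entropy-regularized (Sinkhorn) optimal-transport plan

    min_G ⟨G, Θ⟩_F − H(G)/λ   s.t.  G1 = Pr(C_p̃),  Gᵀ1 = Pr(C_p),

executed on non-fingerprinted cells only. Marked cells are never
touched, so extraction from the robust copy is exact — while the
attacker, who cannot tell marks from ordinary cells, finds no broken
structure left to exploit.

## Worked example

```
printf 'demo-owner-secret' > key.txt
genofp simulate --families 150 --unrelated 1050 --snps 156 \
    --maf 0.25 --ld-r 0.4 --seed 1 --out-prefix pop
genofp protect --db pop.tsv --key-file key.txt --sp-id 7 \
    --gamma-r 0.09 --gamma-l 0.09 --fam pop.fam \
    --s pop.s.json --j pop.j.json --seed 2 \
    --out robust.tsv --mask-out mask.json
genofp attack --mode corr --db robust.tsv --fam pop.fam \
    --s pop.s.json --j pop.j.json --budget 0.25 --seed 3 \
    --out pirated.tsv
genofp evaluate --reference pop.tsv --candidate pirated.tsv \
    --key-file key.txt --sp-id 7 --gamma-r 0.09 --gamma-l 0.09
```

On this 1500 × 156 population (150 mother–father–child trios) the run
prints:

```
{"mendel_repair": {"cells_changed": 155, "loci_skipped": 1},
 "similarity_restore": {"cells_changed": 656, "pairs_exhausted": 5},
 "mitigate_column": {"cells_changed": 902},
 "mitigation_cells_changed": 1713, "mitigation_perchg": 0.0073,
 "total_perchg": 0.0110}
{"row_attack": {"cells_changed": 201, ...}, "col_attack":
 {"cells_changed": 0}, "perchg": 0.00086}
{"acc": 0.9883, "perchg": 0.0117, "percmp": 0.0, "topk_consistency": 0.86}
```

Reading: making the fingerprinted copy robust cost an extra 0.73% cell
changes on top of the 0.37% caused by the marks themselves; the
correlation attack then found almost nothing to repair (0.086% changes),
failed to disturb a single fingerprint bit (`percmp 0.0`), and
`genofp extract --candidates sps.json` ranks SP 7 first with agreement
1.0 against ≈0.46 for innocent SPs. 86% of the top-50 association loci
survive the whole pipeline.

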