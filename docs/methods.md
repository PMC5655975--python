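# Methods

## Model

`bpscan` treats branch-point calling as a constrained scan: the biology
fixes *where* to look (between the first upstream AG and the pyrimidine-rich
3' end of the PPT) and *what* to score (a 7-nt motif whose position 6 is the
branch adenosine, base-paired by U2 snRNA's GUAGUA with the branch base
bulged out). The assumptions are: one branch site per intron is reported
(introns may carry several annotated sites; prediction is correct if it hits
any); the intron is given 5'→3' and ends at the 3'ss AG; and the motif model
is a position-independent 4×7 frequency matrix.

### Coordinates

All positions are 3'ss-relative and negative: −1 is the intron's last base.
This makes distances directly comparable across introns of different
lengths, matching how branch-point positions are reported in the field
(most human branch points fall between −18 and −32).

### PPT detection

A candidate tract must satisfy: (1) pyrimidine 5' and 3' ends; (2) no purine
run longer than 2; (3) every purine segment of length *l* flanked by
pyrimidine segments each ≥ *l* with ≥ 4·*l* pyrimidines in total; (4) T(GT)n
stretches permitted — G's inside a maximal T(GT)n run are treated as
pyrimidines for rules 2–3 (they neither break the tract nor count toward
purine segments, and they count as flanking "pyrimidines"; the termini must
still be literal C/T); (5) length ≥ 9 **or** ≥ 5 T's ("uridine content" is
read as a count, not a fraction). Candidate tracts are non-extendable valid
substrings; selection is 3'-most end first, then longest. The search window
is the AGEZ core (3'ss back to the defining AG, without the L-extension):
the region where a functional PPT can sit. Detection is an exhaustive
substring scan — windows are at most a few hundred nt, so the O(n³) cost is
negligible and exactness is worth more than speed.

### AGEZ and shortened AGEZ

Scanning 5'-ward from position −13 (AGs wholly within the 12 nt adjacent to
the 3'ss are ignored; an AG with its A at −13 counts), the first AG found
defines the zone; the AGEZ runs from *L* nt upstream of that A to −1,
clamped at the intron start, and is the whole intron when no AG exists.
*L* defaults to 9 (valid 7–12): candidate branch points sit a few bases 5'
of the zone-defining AG often enough that the extension is needed, and 9 is
the value at which prediction accuracy peaks. The shortened AGEZ excludes
the PPT's maximal all-pyrimidine suffix — branch sites do not occur inside
that run. The exclusion boundary is not defined numerically anywhere we
know of; the suffix-run rule is one consistent reading and is isolated in
`shorten_agez` so it can be swapped. Only the branch position itself must
lie in the zone; the heptamer may extend past either boundary as long as it
stays inside the intron.

### Scoring

S\*(X) = Σ log₂ f(i, Xᵢ) − [Σⱼ Pⱼ·BE(X/X_{j+4})·f(j+4, X_{j+4})^{Qⱼ}]/ΣⱼPⱼ,
with the j-th energy term tied to k = j+4 (k = 5, 6, 7): the branch site or
a neighbour, since branch positions mapped from cDNA are frequently off by
a base. Zero matrix frequencies give S = −∞ and exclude the candidate
outright — deliberate, no pseudocounts: a TNA-fixed matrix (f(4,T) =
f(6,A) = 1) then admits only TNA heptamers, which is its point. When every
candidate is excluded, the prediction falls back to the candidate with the
most stable BE(X/X₆) duplex and says so in a flag. Fifteen named (P, Q)
configurations live in `src/bpscan/data/score_configs.yaml`. Two are
canonical — score0 (P = 0, pure PSSM) and score8 (P = (0,1,0), Q₂ = 1, the
default operating point; with f(6,X₆) = 1 the score8−score0 gap is exactly
−BE(X/X₆)). The other thirteen sweep the non-empty subsets of {5,6,7} at
Q = 0.5 and Q = 1; they are this package's own systematic parameterization
of the family, provided so the whole family can be compared on any dataset.

Ties at equal score resolve toward the 3'ss, consistent with the observed
concentration of human branch points near the 3' end of the zone.

### Duplex energies

BE(X/X_k) is the minimum free energy of co-folding the k-deleted hexamer
(T→U) with GUAGUA. Backends: `cofold` (ViennaRNA, default Turner parameters
at 37 °C; in-process bindings, falling back to the `RNAcofold` executable),
`nn` (a self-contained fixed-register nearest-neighbor evaluator: best
single helix over all antiparallel registers, Turner 2004 Watson–Crick
stacks, a coarse −1.0 kcal/mol term for any wobble-containing stack, duplex
initiation +4.09, terminal AU/GU +0.45), and `file:` for precomputed
tables. All 4096 hexamer energies are computed once and cached; predictions
are table lookups. Positive MFEs are clamped to 0 kcal/mol so that an
unstable duplex degrades S\* to the pure PSSM score rather than rewarding
instability.

A caveat worth knowing: under free co-folding the perfect GUAGUA complement
(UACUAC, −4.5 kcal/mol) is **not** the global minimum over all hexamers —
GC-rich hexamers pairing in a shifted register reach −5.9 (e.g. GCUACA).
The spliceosome fixes the pairing register; free co-folding does not. The
fixed-register `nn` backend does rank the perfect complement minimal, and
under both backends no single-mismatch neighbour of UACUAC is more stable.
This has little effect on prediction (candidates competing on energy also
compete on the PSSM term) but it is why no "perfect complement is globally
minimal" invariant is enforced on cofold tables.

## Synthetic data

The generator (`bpscan.fixtures`) emulates the 3'-end architecture of a
human intron: a planted branch-point heptamer (consensus TACTAAC or sampled
per-position from a matrix), a downstream pure-pyrimidine PPT with ≥ 5 T's
guarded 5' by a purine, the terminal AG, an AGEZ-defining AG 8 nt upstream
of the branch site, decoy AGs further upstream, and an i.i.d. background at
40% GC (roughly intronic composition). Stray AG dinucleotides 3' of the
defining AG are broken (G→C), as are stray copies of the planted heptamer
(C/T substitutions, which can create neither an AG nor a new copy
undetected), so the planted site is the unique optimum by construction.
Defaults: length 120, branch at −25, PPT length 15, decoys at −70/−90 —
typical values for short human introns, where branch points concentrate at
−18..−32.

What the generator does **not** emulate: positional base-composition
gradients, real PPT length/strength variation, degenerate motifs embedded
in correlated background, multiple true branch sites, or 5'ss context.
Passing the synthetic suite therefore shows the machinery is correct
(regions, scan, scoring, selection), not that real-data accuracy figures
transfer; those are checked separately against the published intron sets
when their files are present (`data/supplementary/README.md`).

The bundled matrices are synthetic stand-ins, one per motif class
(TNA-fixed strict; degenerate ~1.2 bits total IC; genome-wide-style YTNAY
~2.2 bits). They are deliberately not fitted to any published table.

## Numerical choices and degenerate inputs

* Matrix columns must sum to 1 within 1e−3 (then renormalized); anything
  further off is rejected, not silently fixed.
* Information content is IC_i = 2 + Σ f log₂ f (uniform background,
  0·log 0 = 0), so a fixed position contributes 2 bits.
* Heptamers containing N are never scored; introns shorter than 14 nt
  (ignore zone + 3'ss AG) are rejected; an empty shortened AGEZ raises
  rather than returning an empty scan.
* Equal PPT candidates: 3'-most end, then longest. Equal S\*: 3'-most
  branch position. Both rules are deterministic, so repeated runs are
  byte-identical.
* Accuracy is rounded to 2 decimals; per-intron verdicts are emitted so
  rounding never hides a changed call.

## Problem sizes

The test suite and `scripts/acceptance.py` use 200-intron synthetic
cohorts, 10⁴-string oracle comparisons for the PPT finder and 100-fixture
end-to-end oracle comparisons — sizes at which every stochastic quantity
reported has settled to within a percent or two while the whole suite runs
in seconds.

## Known limitations

* The Hamming and full-AGEZ-PWM baselines use this package's tie-breaking
  (toward the 3'ss); the original methods' rules may differ by ±1 intron on
  real sets.
* The exact (P, Q) values of the thirteen non-canonical family members are
  this package's parameterization; results quoted for them are not
  comparable across tools.
* The PPT-suffix rule for the shortened-AGEZ boundary is an interpretation;
  a different boundary shifts the zone's 3' end by a few bases.
* Branch-site annotation format (`bp=` header token) is this package's
  convention; converters are needed for other encodings.
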