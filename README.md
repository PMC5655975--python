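# bpscan

Branch-point-sequence (BPS) prediction for human introns.

During pre-mRNA splicing the U2 snRNP base-pairs its conserved GUAGUA motif
with a ~7-nt intronic branch point sequence, bulging out the branch-site
adenosine that attacks the 5' splice site. In human introns the BPS is
degenerate and hard to call from sequence alone. `bpscan` implements a
heuristic predictor for it, aimed at anyone who needs per-intron branch-site
calls from intron sequences: it

1. finds the **polypyrimidine tract** (PPT) under five structural rules
   (pyrimidine ends, no purine run > 2, flanking-pyrimidine requirements for
   purine segments, T(GT)n stretches allowed, length ≥ 9 or ≥ 5 uridines),
   picking the maximal tract closest to the 3' splice site;
2. builds the **AG exclusion zone** (AGEZ): from the 3'ss back to the first
   upstream AG dinucleotide (ignoring AGs in the 12 nt next to the 3'ss),
   extended a further *L* (= 9 by default) nt upstream; the zone minus the
   PPT's pyrimidine-rich 3' end is the **shortened AGEZ**, the search space;
3. scores every candidate heptamer *X* (branch adenosine at position 6) in
   the shortened AGEZ with the **S\*** family

   S\*(X) = Σᵢ₌₁⁷ log₂ f(i, Xᵢ) − [ Σⱼ₌₁³ Pⱼ · BE(X/X_{j+4}) · f(j+4, X_{j+4})^{Qⱼ} ] / Σⱼ Pⱼ

   combining a PSSM term over a 4×7 frequency matrix f, the co-folding
   minimum free energy BE(X/X_k) of the k-deleted hexamer against GUAGUA
   (ViennaRNA RNAcofold, kcal/mol), and the branch-site base preference
   f(k, X_k). `score0` (P = 0) is the pure PSSM score; the default `score8`
   activates only the branch-site term: S\* = S − BE(X/X₆)·f(6, X₆);
4. reports the top-scoring heptamer's position-6 coordinate (3'ss-relative,
   −1 = last intron base) as the branch site, ties resolved toward the 3'ss.

An evaluation harness (exact-position accuracy with an any-of rule for
multi-site introns), fixed-window Hamming-to-TACTAAC baselines, a full-AGEZ
PWM baseline, and a deterministic synthetic-intron generator are included.

## Worked example

```bash
bpscan simulate --n 3 --seed 7 --out demo.fa
bpscan predict --fasta demo.fa --matrix tna-strict --score score8 -L 9 \
       --energy-backend cofold --out demo_pred.tsv
cat demo_pred.tsv
```

```
# bpscan v0.1.0
# score=score8 matrix=bundled:tna-strict (synthetic) energy-backend=cofold
intron_id	heptamer	branch_pos	score	score_name	ppt_start	ppt_end	agez_start	short_agez_start	short_agez_end	flag
fix000-seed2029167940	TACTAAC	-25	3.3277	score8	-17	-3	-42	-42	-18	.
fix001-seed1342382291	TACTAAC	-25	3.3277	score8	-17	-3	-42	-42	-18	.
fix002-seed1469265225	TACTAAC	-25	3.3277	score8	-19	-3	-42	-42	-18	.
```

Each simulated intron carries the consensus heptamer TACTAAC with its branch
adenosine planted at −25; the predictor finds the PPT (e.g. −17..−3), the
AGEZ (−42..−1), shortens it to −42..−18, and calls the branch site at −25
with S\* = 3.33 (PSSM score −1.17 bits minus the −4.5 kcal/mol consensus–
GUAGUA duplex energy). Scoring against the annotations:

```bash
bpscan evaluate --fasta demo.fa --matrix tna-strict --out demo_report.tsv
# -> 3/3 correct (100.00%)
```

`bpscan regions` emits the interval table, `bpscan baseline` the Hamming
baselines, and `bpscan energy-table` the 4096-hexamer GUAGUA energy table.
The same functionality is available as a library (`bpscan.predict`,
`bpscan.find_ppt`, `bpscan.find_agez`, ...).

The bundled matrices (`tna-strict`, `degenerate`, `genomewide`) are
synthetic stand-ins emulating the three motif classes (TNA-fixed, degenerate
YUNAY-like, genome-wide YTNAY-like); to evaluate against the published
verified-intron datasets and their frequency tables, place those files under
`data/supplementary/` as described there.

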