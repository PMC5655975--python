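# Published evaluation data (not redistributed)

The full evaluation protocol compares predictions against two sets of
experimentally verified human introns and three published heptamer
frequency tables. Those files are supplementary material of the article
this evaluation reproduces (doi:10.1186/s12859-017-1864-9) and are not
redistributed here. To enable the protocol checks in
`tests/test_acceptance.py`, place the following files in this directory:

| file           | content                                                    |
|----------------|------------------------------------------------------------|
| `Dataset_S1.fa` | 42 verified introns (Additional file 2), FASTA             |
| `Dataset_S2.fa` | 88 curated introns (Additional file 3), FASTA              |
| `Table_S4.tsv` | 4x7 relative-frequency matrix of the Dataset S1 heptamers  |
| `Table_S5.tsv` | 4x7 relative-frequency matrix of the Dataset S2 heptamers  |
| `Table_S6.tsv` | 4x7 matrix from sequencing-mapped branch points (type II)  |

Format notes:

* Intron FASTA records must end at the 3'ss AG and carry the branch-site
  annotation in the header as a `bp=` token of comma-separated negative
  3'ss-relative positions, e.g. `>intron7 bp=-24,-31`. Convert whatever
  encoding your copy of the supplementary FASTA uses into this form.
* Matrix TSVs use a header `pos1..pos7` and row labels A/C/G/T (or the
  transpose; orientation is auto-detected), with relative frequencies that
  sum to 1 per position.

When any file is missing, the corresponding checks skip with a notice
naming the absent paths; everything else in the test suite runs on
generated synthetic data.
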