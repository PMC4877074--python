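# rnacurve

Alignment-free comparison and classification of RNA secondary structures
through a dynamic 3D graphical representation.

A structure (sequence + base pairs, pseudoknots allowed) is:

1. **encoded** into an 8-letter *characteristic sequence* — unpaired
   bases stay `A G C U`, bases inside a pair are primed (written
   lowercase `a g c u` in text files);
2. **unfolded** into three 3D curves, one per chemical 2-way grouping of
   the bases — amino/keto (M-K), purine/pyrimidine (R-Y), weak/strong
   H-bond (W-S).  The X-Y projection of every curve point lies on the
   unit circle (sign of x encodes paired/unpaired, sign of y the
   chemical group); z accumulates group counts along the sequence;
3. **collapsed** into a 36-component descriptor: the geometric center
   (mean x, y, z) of each of the four group-sets of each curve;
4. **compared** by the quotient of the Euclidean distance between two
   descriptors and the cosine of the angle between them (0 = identical,
   larger = more dissimilar); pairwise matrices feed a deterministic
   UPGMA implementation with Newick output and cluster-purity scoring.

A seeded synthetic generator produces valid random structures
(canonical A-U/G-C/G-U pairs, optional crossing pairs) and mutated
family datasets so the whole pipeline is testable without downloads.

## CLI

```sh
# encode structures (dot-bracket / CT / BPSEQ) to characteristic sequences
rnacurve encode --in structures.dbn --format dotbracket --out encoded.fasta

# per-point curve coordinates, optionally plotted
rnacurve curves --in structures.dbn --map mk --out points.tsv --plot curves.png

# 36-component descriptors, one CSV row per record
rnacurve vectorize --in encoded.fasta --format characteristic --out vectors.csv

# pairwise quotient-similarity matrix (square PHYLIP, optional CSV)
rnacurve compare --in structures.dbn --out matrix.phylip --csv matrix.csv

# UPGMA tree and cluster-purity report
rnacurve tree --matrix matrix.phylip --out tree.nwk \
    --families families.tsv --purity-report

# synthetic data: single structures or family datasets
rnacurve simulate --families 5 --per-family 4 --divergence 0.05 \
    --n 120 --seed 1 --out simdir/
```

## Layout

| module | contents |
| --- | --- |
| `rnacurve.structure_io` | dot-bracket / CT / BPSEQ parsers, characteristic-sequence encode/decode |
| `rnacurve.curves` | group schemes, cumulative counts, the three 3D curves |
| `rnacurve.descriptor` | 36D geometric-center descriptor, composition summary |
| `rnacurve.similarity` | distance/cosine quotient, pairwise matrices, PHYLIP/CSV I/O |
| `rnacurve.tree` | UPGMA, Newick, monophyly-based cluster purity |
| `rnacurve.synthetic` | seeded random structures and family datasets |
| `rnacurve.cli` | `rnacurve` command-line interface |
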