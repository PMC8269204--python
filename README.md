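# halomotif

Discovery and functional classification of **flavin-dependent halogenases
(FDHs)** from protein sequence sets.

FDHs install chlorine or bromine on aromatic substrates using FAD, O₂ and a
halide ion, and are prized biocatalysts because they do so regioselectively.
Tryptophan halogenases (Trp-FDHs) in particular are subclassified by the
indole-ring carbon they halogenate (C5, C6 or C7), yet public sequence
repositories routinely mislabel them because annotation by homology transfer
cannot see such subtle functional differences.  `halomotif` implements, as a
transparent library and command-line tool, a sequence-level workflow that
can:

1. **find FDH candidates** in a protein set with a profile hidden Markov
   model (pHMM) built from seed alignments, scored by forward log-odds with
   an explicit Gumbel E-value calibration and filtered on E-value and model
   coverage;
2. **embed and classify** candidates by per-group positional probabilities:
   for six halogenase groups (5-, 6-, 7-Trp, indole, phenolic, pyrrole) the
   probability of the query's residue at each profile column is a feature;
   t-SNE gives a 2-D map and 1-nearest-neighbour assigns the cluster
   (A1/A2/B1/B2/C);
3. **locate conserved functional regions** by a sliding 3-mer Shannon
   entropy screen over a seed alignment, labelling the ten known sites
   (FAD1–4, catalytic Lys, halide, Trp1–4) with degenerate anchor motifs;
4. **call substrate scope and regioselectivity** from the Trp1–4 motif
   grammar: Trp4 presence/length separates non-Trp (C), 7/6-Trp (A) and
   5/6-Trp (B) enzymes, and sub-patterns of Trp1–Trp4 resolve A1→C7, A2→C6,
   B1→C5, B2→C6, with a weighted vote and a nearest-neighbour fallback;
5. **check enzyme–substrate contacts** in PDB coordinate files (e.g. the
   Gln side chains of a Trp3 motif against a bound tryptophan's
   carboxylate oxygens).

The package bundles the catalogue of 34 experimentally characterized
halogenases (groups, regioselectivities, motif strings), the 13 seed
accessions of the tryptophan-halogenase family, an editable anchor-motif
table, and a deterministic synthetic sequence family for testing everything
offline.

## Worked example

Classify the pyrrolnitrin halogenase PrnA and the 5-Trp halogenase PyrH from
their motif strings:

```python
from halomotif.motif_caller import classify_by_motifs, motifset

prna = classify_by_motifs(motifset(
    "PrnA", "ATIPSL", "HLFGN", None, "YYETFDFEFKNFWLNGNYY"))
pyrh = classify_by_motifs(motifset(
    "PyrH", "ATFSTV", "HPFER", "QRAQ", "YYHGFETYS"))
print(prna.group, prna.regioselectivity, f"{prna.confidence:.2f}")
print(pyrh.group, pyrh.regioselectivity, f"{pyrh.confidence:.2f}")
```

prints

```
A1 7 1.00
B1 5 1.00
```

PrnA's 19-residue Trp4 ending `...GNYY` plus its `ATIP`/`HLF` Trp1/Trp2
patterns vote unanimously for cluster A1, hence halogenation at C7 of
tryptophan.  PyrH's 9-residue Trp4 with `FE` at positions 5–6, the `QxxQ`
Trp3 spacing and the `...STV`/`HPFER` tails all vote B1, hence C5.

An end-to-end run on a synthetic candidate set:

```bash
halomotif fixtures --what synthetic --out queries/ --seed 7 --n 10
printf 'seed: 7\n' > run.yml
halomotif run --config run.yml --fasta queries/synthetic.faa --out results/
```

writes `hits.tsv` (screening scores, E-values, coverage), `features.tsv`,
`embedding.tsv`, `regions.tsv` (conserved regions with site labels) and
`calls.tsv` (group, regioselectivity, motifs and per-rule evidence for every
retained query).

## Layout

```
src/halomotif/
  seqio.py            FASTA/Stockholm I/O, alphabet validation
  profile_hmm.py      pHMM build, forward/Viterbi, E-value calibration, scanning
  group_profiles.py   positional-probability features, t-SNE, 1-NN
  motif_discovery.py  3-mer entropy screen, conservation, site labelling
  motif_caller.py     Trp1-4 motif extraction and grammar
  structure_check.py  PDB parsing, contact distances
  fixtures.py         bundled tables + synthetic family generator
  pipeline.py, cli.py end-to-end wiring and the `halomotif` command
  data/               table1.tsv, seed_accessions.tsv, anchors.tsv
```

See `docs/methods.md` for the models, parameter choices and limitations.
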