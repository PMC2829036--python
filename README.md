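# motifarch

Toolkit for analysing the short conserved microdomains of nuclear-receptor
N-terminal isoform-specific regions (ecdysone-receptor A and B1 isoforms):

* **motif grammar** — degenerate consensus patterns (fixed residues, `x`
  wildcard, `(X/Y)` alternations, the large-hydrophobic `Ψ` class) and
  compositional scanning for low-complexity elements (S-rich, DL-rich);
* **annotator** — scans a sequence with the full motif catalog, enforces
  positional constraints (N-/C-terminal windows, the SP dipeptide between
  the S-rich and DL-rich motifs), retains one best hit per motif class and
  flags architecture violations;
* **classifier** — priority-ordered decision tables assigning each region
  one of five A structural types or seven B1 structural types
  (`A1..A5`, `B1-1`, `B1-2`, `B1-2'`, `B1-3..B1-6`), with optional taxon
  metadata for documented subgroup exemptions;
* **profiles** — consensus strings and information-content logos from
  alignments of motif instances;
* **phylo** — Fitch parsimony reconstruction of motif gain/loss on a rooted
  taxon tree (a default order-level insect cladogram is bundled), with an
  optional Dollo mode;
* **synthetic** — a ground-truthed exemplar generator for all twelve
  structural-type templates, built from the printed per-type consensus
  sequences, with configurable linkers and substitution noise.

The motif catalog ships as editable YAML (`src/motifarch/data/catalog.yaml`);
run-time thresholds live in a separate config (`motifarch.config.RunConfig`,
overridable from YAML). All coordinates in reports are 1-based inclusive
(GFF3-compatible).

## CLI

```sh
# generate a ground-truthed panel (FASTA + GFF3 + label TSV)
motifarch simulate --template all-B1 --n 5 --noise 0.05 --seed 42 --out panel

# annotate sequences with the motif catalog
motifarch annotate --fasta panel.fasta --isoform B1 \
    --out-gff hits.gff3 --out-tsv hits.tsv

# assign structural types (optional taxon table: id <TAB> taxon)
motifarch classify --fasta panel.fasta --isoform B1 --out types.tsv

# consensus/logo from an aligned FASTA
motifarch consensus --fasta aligned.fasta --out-profile profile.tsv --logo logo.png

# gain/loss reconstruction (bundled insect-order tree by default)
motifarch evolve --states states.tsv --out-events events.tsv \
    --out-tree annotated.nwk --dollo
```

Exit codes: 0 success, 2 input error, 3 configuration error.

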