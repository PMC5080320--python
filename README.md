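# indelphase

Phylogenetic tests for **conservation and acceleration of insertion/deletion
rates**, independent of nucleotide substitution rates, over sets of
gene-family alignments.

The package fits gap-extended substitution models by maximum likelihood
across many alignment/tree pairs and then tests every alignment column with
two likelihood-ratio tests:

| test    | comparison                                            | score  |
|---------|-------------------------------------------------------|--------|
| `subst` | F84 vs F84 with a free branch-length scale `rho`      | phyloP-style |
| `indel` | relaxed gap-extended F84 vs the same model with a free scale `rho_indel` on the indel rates | indelP |

Models implemented:

- **F84** — classic 4-state substitution model (`alpha`, `beta`), gaps as
  missing data;
- **HKY+G** — HKY85 with the gap as a fifth character exchanged at rate
  `sigma * pi` (provided mainly to demonstrate its inverted
  insertion/deletion balance on deletion-biased data);
- **F84e-relaxed** — F84 residue block plus a per-site deletion rate `mu`
  and insertion rate `lambda`, a geometric ancestral-length prior `p`, and
  gap treated as an observed state in the pruning recursion, with multiple
  insertions per column allowed.

Supporting machinery: Felsenstein pruning over the 5-state alphabet with the
ancestral-length prior and observability correction, marginal / joint /
subtree ancestral reconstruction with implicit-parsimony indel counting (the
deletion/insertion length ratio weights the per-site insertion scaling), a
forward simulator with recorded event truth, and plain-text I/O (FASTA,
Newick, TSV score tables, key-value model files).

## Command line

Every subcommand logs to stderr, writes machine output only to files, and is
deterministic given identical inputs and `--seed`.

```sh
# simulated benchmark bundle (FASTA + Newick + truth JSON per family)
indelphase simulate --families 50 --columns 300 --taxa 10 \
    --lam 0.01 --mu 0.06 --seed 1 --out-dir data/

# keep/drop manifest: gap-run, species and size filters
indelphase filter --data-dir data/ --max-gap-run 30 --min-sequences 5 \
    --out manifest.tsv

# global maximum-likelihood fit (F84 | HKYG | F84E_RELAXED)
indelphase fit --data-dir data/ --model F84E_RELAXED --out model.txt

# ancestral indel-event counts and D/I ratio
indelphase count --data-dir data/ --model model.txt --out events.tsv

# per-column LRTs: score TSV(s) + summary JSON (+ overlap table)
indelphase score --data-dir data/ --model model.txt \
    --tests indel,subst --out-dir scores/
```

A directory of paired `<family>.fa` / `<family>.nwk` files is the exchange
format throughout. Scores are reported per family with 1-based columns; the
signed score is `-log10(p)` for acceleration (scale > 1) and `log10(p)` for
conservation (scale < 1); `--phast-sign` flips the convention.

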