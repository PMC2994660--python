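# coevoscan

Molecular-evolution selection scans for protein-coding genes, plus a
hybrid-genome ChIP-Seq window-enrichment pipeline — the computational
toolkit for studying how a fast-evolving chromatin regulator diverges
between closely related yeast species, with simulators so every stage
runs without external data.

## Who this is for

Analyses of this shape arise when a gene (here, the silent-chromatin
scaffold *SIR4* of the *Saccharomyces sensu stricto* clade) shows
unusually rapid divergence and one wants to know **where** in the gene
selection acts, **which lineages** it acts on, and whether the protein's
genomic binding behavior differs between species.  The package
re-implements that analysis stack as a tested library:

- **dN/dS (ω) estimation** under the Goldman–Yang codon model: a
  single-ratio fit (M0) of ω = dN/dS with κ and branch lengths
  estimated by maximum likelihood;
- **positive-selection site tests**: the beta site-mixture M7 vs the
  beta-plus-ω_s mixture M8, compared with a likelihood-ratio test
  (2Δℓ vs χ²₂), and Bayes Empirical Bayes (BEB) per-codon posterior
  probabilities of ω > 1;
- **sliding-window scans**: ω in 102 bp windows every 3 bp along the
  gene, read against an empirical null of same-sized windows from
  background genes;
- **branch models**: a free-ratio fit assigning an independent ω to
  every branch;
- **ortholog divergence summaries**: length-weighted percent identity
  over homology-search HSPs and the genome-wide 5%-bin histogram;
- **ChIP-Seq enrichment** over a two-species hybrid genome: per-base
  coverage, 100 bp / 50 bp sliding-window medians, per-base and
  windowed IP/Input ratios, and 600 bp region means normalized to a
  control region;
- **simulators** for codon alignments (M0 / M7 / M8 / per-branch ω,
  with per-site truth) and for IP/input coverage tracks with planted
  fold enrichment.

## The model in brief

The rate from codon *i* to *j* (61 sense codons, universal code) is
0 for multi-nucleotide changes and otherwise π_j · κ^[transition] ·
ω^[nonsynonymous], scaled to one expected substitution per codon per
unit branch length (mixture-averaged across site classes for M7/M8).
ω < 1 indicates purifying selection, ω ≈ 1 neutrality, ω > 1 positive
selection.  M7 draws site ω from a discretized Beta(p, q) on (0, 1);
M8 adds a class at ω_s ≥ 1 holding proportion 1 − p0 of sites; 2Δℓ
between them tests for positively selected sites, and BEB integrates
the per-site posteriors over a grid prior on (p0, p, q, ω_s).  See
`docs/methods.md` for the full specification and numerical choices.

## Worked example

Simulate a 5-taxon gene with 5% of codons under strong positive
selection, then run the site test:

```python
from coevoscan import PhyloTree, SimSpecCodon, simulate_codon_alignment
from coevoscan.site_models import site_test, beb_site_posteriors

tree = PhyloTree.five_taxon_default()          # sensu-stricto-shaped
spec = SimSpecCodon(tree, "M8",
                    {"kappa": 2.0, "p0": 0.95, "p": 0.5, "q": 2.0,
                     "omega_s": 5.0},
                    n_codons=1000, seed=7)
aln, truth = simulate_codon_alignment(spec)

fit7, fit8, lrt = site_test(aln, tree, optimize_branch_lengths=False,
                            n_starts=1)
print(f"2dlnL = {lrt.statistic:.1f}  df = {lrt.df}  p = {lrt.p_value:.2e}")
print(f"M8: p0 = {fit8.mixture.p0:.3f}  omega_s = {fit8.mixture.omega_s:.2f}")

beb = beb_site_posteriors(aln, tree, fit8, threshold=0.75)
flagged = beb[beb.flagged]
hits = truth.loc[flagged.site, "selected"]
print(f"{len(flagged)} codons flagged at P(omega>1) >= 0.75; "
      f"{hits.sum()} of them truly selected")
```

Output:

```
2dlnL = 86.6  df = 2  p = 1.58e-19
M8: p0 = 0.951  omega_s = 4.11
33 codons flagged at P(omega>1) >= 0.75; 31 of them truly selected
```

The test strongly rejects the no-selection model, the mixture estimates
land near their generating values (p0 = 0.95, ω_s = 5), and the flagged
codons are overwhelmingly the truly selected ones.

The same stages are exposed as a CLI for file-based work:

```bash
coevoscan fit-m0     --alignment gene.fasta --tree tree.nwk
coevoscan site-test  --alignment gene.fasta --tree tree.nwk --k 10 --beb-threshold 0.75
coevoscan branch-scan --alignment gene.fasta --tree tree.nwk
coevoscan window-scan --alignment gene.fasta --tree tree.nwk --window 102 --step 3
coevoscan identity   --hsps hits.tsv --bin 5
coevoscan chip       --ip ip.bedgraph --input input.bedgraph \
                     --regions regions.bed --control-label Sb-Control
coevoscan simulate codon --spec spec.json --out simdir/
```

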