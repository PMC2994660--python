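"""Workflow sketch for the real-sequence gene analysis.

Expects in this directory (user-supplied; see README.md):
    sir4_protein_alignment.fasta   aligned amino-acid sequences, 5 taxa
    sir4_cds.fasta                 unaligned coding DNA, same taxa
    sensu_stricto.nwk              species tree (branch lengths optional)
    sir4_hits.tsv                  optional BLASTP outfmt-6 table

Run:  python repro/run_sir4.py
"""

import pathlib
import sys

from coevoscan import (PhyloTree, backtranslate, build_empirical_null,
                       fit_M0, fit_free_ratio, scan_omega, summarize_scan)
from coevoscan.io import read_fasta
from coevoscan.site_models import beb_site_posteriors, site_test

HERE = pathlib.Path(__file__).parent


def main() -> None:
    needed = ["sir4_protein_alignment.fasta", "sir4_cds.fasta",
              "sensu_stricto.nwk"]
    missing = [n for n in needed if not (HERE / n).exists()]
    if missing:
        sys.exit(f"missing inputs (see repro/README.md): {missing}")

    prot = read_fasta(HERE / "sir4_protein_alignment.fasta")
    cds = read_fasta(HERE / "sir4_cds.fasta")
    aln = backtranslate(prot, cds)
    tree = PhyloTree.from_newick(str(HERE / "sensu_stricto.nwk"))

    m0 = fit_M0(aln, tree)
    print(f"whole-gene omega = {m0.params.omega:.3f} "
          f"(kappa = {m0.params.kappa:.2f}, lnL = {m0.lnL:.2f})")

    fit7, fit8, lrt = site_test(aln, tree)
    print(f"M7 vs M8: 2dlnL = {lrt.statistic:.2f}, p = {lrt.p_value:.2e}")
    beb = beb_site_posteriors(aln, tree, fit8, threshold=0.75)
    flagged = beb[beb.flagged]
    print(f"{len(flagged)} codons with P(omega>1) >= 0.75:")
    print(flagged.to_string(index=False))

    scan = scan_omega(aln, tree, window_size=102, step=3)
    print("window scan:", scan.summary)

    free = fit_free_ratio(aln, tree)
    print("per-branch omega:", {k: round(v, 3)
                                for k, v in free.branch_omegas.items()})

    hits = HERE / "sir4_hits.tsv"
    if hits.exists():
        from coevoscan.divergence import read_hsp_table, summarize_pairs
        for s in summarize_pairs(read_hsp_table(hits)):
            print(s.pair_id, "weighted identity:",
                  None if s.no_hit else round(s.weighted_identity, 1))


if __name__ == "__main__":
    main()
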