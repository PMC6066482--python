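"""Genetics stage: QC, HWE, case-control association, SNP screen, LD.

Reproduces the published case-control arithmetic from the printed
genotype counts (cases 202/511/319 vs controls 688/1409/766 for
AA/AG/GG), then runs the same machinery on the synthetic cohort: per-SNP
call-rate filter, HWE per group, genotypic/allelic association with the
allele odds ratio, and the additive imaging-genetics screen (main
effect, gene x addiction interaction, within-group effects) on the mean
Diff-connection strength.
"""

import argparse
from pathlib import Path

import pandas as pd

from rewardnet import io
from rewardnet.popgen import (allele_frequencies, call_rate_filter,
                              case_control_association, hwe_chisq,
                              ld_pairwise, snp_screen)

ROOT = Path(__file__).resolve().parents[1]

PUBLISHED_HA = (202, 511, 319)
PUBLISHED_HC = (688, 1409, 766)


def published_block() -> None:
    res = case_control_association(PUBLISHED_HA, PUBLISHED_HC)
    print("published rs279858 counts reanalysed:")
    print(f"  genotypic chi2 = {res.genotypic_chi2:.2f} (p = {res.genotypic_p:.3f})")
    print(f"  allelic chi2 = {res.allelic_chi2:.2f} (p = {res.allelic_p:.2g})")
    print(f"  allele-A OR = {res.odds_ratio:.2f} "
          f"(95% CI {res.ci_lower:.2f}-{res.ci_upper:.2f})")
    print(f"  case freq(A) = {allele_frequencies(PUBLISHED_HA)[0]:.2f}; "
          f"HWE p: cases {hwe_chisq(PUBLISHED_HA)[1]:.2f}, "
          f"controls {hwe_chisq(PUBLISHED_HC)[1]:.2f}")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--min-call-rate", type=float, default=0.98)
    args = ap.parse_args()

    published_block()

    subjects = io.read_subjects(ROOT / "results" / "cohort" / "subjects.tsv")
    table = io.read_genotypes_tsv(ROOT / "results" / "cohort" / "genotypes.tsv")
    table, qc = call_rate_filter(table, args.min_call_rate)
    print(f"\nsynthetic cohort: {int(qc.kept.sum())}/{len(qc)} SNPs pass "
          f"call rate > {args.min_call_rate}")

    strengths = io.read_edge_strengths(
        ROOT / "results" / "network" / "edge_strengths.tsv")
    diff_labels = [
        line.strip() for line in
        (ROOT / "results" / "network" / "diff_edges.txt").read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    phenotype = strengths[diff_labels].mean(axis=1)
    groups = subjects["group"]

    out = ROOT / "results" / "genetics"
    rows = []
    for snp in table.snps:
        ha = table.genotype_counts(snp.snp_id, list(groups[groups == "HA"].index))
        hc = table.genotype_counts(snp.snp_id, list(groups[groups == "HC"].index))
        res = case_control_association(ha, hc)
        rows.append({"snp": snp.snp_id,
                     "ha_hwe_p": hwe_chisq(ha)[1], "hc_hwe_p": hwe_chisq(hc)[1],
                     "allelic_chi2": res.allelic_chi2, "allelic_p": res.allelic_p,
                     "odds_ratio": res.odds_ratio})
    assoc = pd.DataFrame(rows)
    io.write_tsv(assoc, out / "association.tsv", header=io.provenance_header())

    screen = snp_screen(phenotype, table, groups,
                        covariates=subjects[["age", "cigarettes_per_day"]])
    sdf = pd.DataFrame([r.__dict__ for r in screen])
    io.write_tsv(sdf, out / "screen.tsv", header=io.provenance_header())
    print(f"screen on mean Diff-connection strength ({len(diff_labels)} edges):")
    for r in screen:
        print(f"  {r.snp_id}: main p = {r.main_p:.2g}, "
              f"interaction p = {r.interaction_p:.2g}, "
              f"HA p = {r.case_p:.2g}, HC p = {r.control_p:.2g}")

    ids = [s.snp_id for s in table.snps]
    if len(ids) > 1:
        for k in range(len(ids) - 1):
            res = ld_pairwise(table, ids[k], ids[k + 1])
            print(f"  LD {ids[k]} x {ids[k+1]}: D' = {res.d_prime:.2f}, "
                  f"r2 = {res.r_squared:.2f}")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
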