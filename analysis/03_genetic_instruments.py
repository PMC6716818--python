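#!/usr/bin/env python
"""Instrument validity checks: per-allele gene-exposure effects,
allele-score strength (F-statistics), Hardy-Weinberg tests, and the
confounder-balance table for each cohort.

Expected pattern: every SNP passes HWE, the main synthesis score has
F >> 10, and no covariate associates with dosage beyond chance.
"""

import click

from vitdmr.cohort_io import write_results
from vitdmr.pipeline import PRESET_INSTRUMENTS, genetic_stage

from _paths import COHORTS, RESULTS_DIR, load_cohort


@click.command()
def main():
    for name, (preset, _) in COHORTS.items():
        cohort = load_cohort(name)
        rep = genetic_stage(cohort, PRESET_INSTRUMENTS[preset])
        out = RESULTS_DIR / f"genetic_{name}.json"
        write_results(rep, out)
        click.echo(f"{name}:")
        for snp, row in rep["per_snp"].items():
            click.echo(
                f"  {snp}: beta {row['beta']:+.3f} nmol/L per allele "
                f"(SE {row['se']:.3f}), F={row['F']:.0f}, HWE p={row['hwe_p']:.2f}"
            )
        for label, row in rep["scores"].items():
            flag = " (WEAK)" if row["weak"] else ""
            click.echo(
                f"  {label} [{'+'.join(row['snps'])}]: beta {row['beta']:.3f}, "
                f"F={row['F']:.0f}{flag}"
            )
        n_assoc = sum(
            (tab["p"] < 0.05).sum() for tab in rep["confounder_balance"].values()
        )
        n_tests = sum(len(tab) for tab in rep["confounder_balance"].values())
        click.echo(f"  confounder balance: {n_assoc}/{n_tests} nominal associations")
        click.echo(f"  -> {out}")


if __name__ == "__main__":
    main()
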