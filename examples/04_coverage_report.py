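"""The headline statistic: per-clade sequenced genome fractions.

Runs the full pipeline on a synthetic study, then prints one line per
collapsed cluster: OTU count, genome-backed OTU count, the fraction,
and the sequenced/unsequenced call (strictly below 1% = unsequenced).
The cohort summary (min / median / IQR over sequenced clusters) shows
how unevenly genomes sample the diversity even where they exist.
"""

from divcover.pipeline import run_study
from divcover.simulate import StudyConfig, simulate_study

bundle = simulate_study(StudyConfig(seed=1))
result = run_study(bundle)

print(f"{'cluster':<10}{'OTUs':>6}{'genomes':>9}{'fraction':>10}  status")
for clade in result.coverage.clades:
    print(
        f"{clade.cluster_label:<10}{clade.n_otus:>6}"
        f"{clade.n_genome_backed_otus:>9}{float(clade.fraction):>10.3f}"
        f"  {clade.status}{'' if clade.monophyletic else ' (paraphyletic)'}"
    )
print(f"\nunsequenced clusters: {result.coverage.n_unsequenced} "
      f"of {result.coverage.n_total_clusters}")
mn, med, iqr = result.coverage.summary_over_sequenced
print(f"over sequenced clusters: min={mn:.3f} median={med:.3f} IQR={iqr:.3f}")
print(f"matches planted truth: "
      f"{ {c.cluster_label: c.fraction for c in result.coverage.clades} == bundle.truth.true_fractions }")
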