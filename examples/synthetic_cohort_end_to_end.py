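"""Full pipeline on a synthetic cohort with planted driver sites.

A random 20-gene coding model is mutated in 400 patients at a neutral rate
of 5e-3 expected mutations per site, with three planted driver site-alleles
at per-patient prevalences of 2-6%.  The pipeline then recovers the drivers:
QC, annotation, recurrence tally, neutral calibration, i* and CDN calling,
followed by precision/recall against the generator's ground truth and the
per-patient burden table.
"""

from cdnscan.burden import burden_table
from cdnscan.caller import call_cdns
from cdnscan.coding import annotate_mutations, count_sites
from cdnscan.io import QCConfig, apply_qc_filters, consolidate_patients
from cdnscan.neutral import compute_istar, estimate_rates
from cdnscan.simulate import (
    SimConfig,
    enumerate_site_alleles,
    evaluate_calls,
    make_cds_model,
    simulate_cohort,
)
from cdnscan.spectrum import tally_spectrum

model = make_cds_model(gene_count=20, lengths=150, seed=7)
missense = enumerate_site_alleles(model).query("consequence == 'missense'").site_key
planted = [(missense.iloc[10], 0.06), (missense.iloc[500], 0.04), (missense.iloc[900], 0.02)]
cfg = SimConfig(n=400, nEu=5e-3, planted=planted, seed=11)

table, truth = simulate_cohort(cfg, model)
filtered, report = apply_qc_filters(table, QCConfig())
consolidated = consolidate_patients(filtered)
annotated = annotate_mutations(consolidated, model)
spec = tally_spectrum(annotated, count_sites(model), cfg.n)
fit = estimate_rates(spec)
istar = compute_istar(spec.L_A, fit.q)
cdns = call_cdns(spec, istar)
precision, recall, fp = evaluate_calls(cdns, truth)

print(f"cohort: {len(table)} mutation records in {cfg.n} patients, {report.records_in - report.records_out} removed by QC")
print(f"neutral fit: q={fit.q:.4f} (truth {cfg.nEu / (1 + cfg.nEu):.4f}), i*={istar}")
print(f"called {len(cdns)} CDNs: " + ", ".join(f"{c.site_key} (i={c.i})" for c in cdns))
print(f"precision={precision}, recall={recall:.2f}, false positives={fp}")

cdn_level, gene_level = burden_table(annotated, cdns, cfg.n)
print(
    f"patient burden (CDN level): n_0={cdn_level.n_0} n_1={cdn_level.n_1} "
    f"n_2={cdn_level.n_2} n_>2={cdn_level.n_gt2}, mean {cdn_level.mean:.2f}"
)
print(
    "\nThe planted sites recur far above the neutral tail, so they are called"
    "\nat i*; precision below 1 would flag neutral sites drifting over the"
    "\nthreshold, which the null makes improbable by construction."
)
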