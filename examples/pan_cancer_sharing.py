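"""Cross-cancer sharing of recurrent sites on synthetic cohorts.

Three synthetic cancer types share one planted driver site (prevalent in
all three) while a second driver is specific to the first type.  The
sharing matrix classifies each site by i_max (largest recurrence anywhere)
and the number of types where it reaches the calling threshold.
"""

from cdnscan.coding import annotate_mutations, count_sites
from cdnscan.pancancer import build_site_matrix, sharing_stats
from cdnscan.simulate import SimConfig, enumerate_site_alleles, make_cds_model, simulate_cohort
from cdnscan.spectrum import tally_spectrum

model = make_cds_model(gene_count=8, lengths=120, seed=19)
missense = enumerate_site_alleles(model).query("consequence == 'missense'").site_key
shared, private = missense.iloc[40], missense.iloc[300]

specs = []
for t, label in enumerate(["type_a", "type_b", "type_c"]):
    planted = [(shared, 0.05)] + ([(private, 0.06)] if label == "type_a" else [])
    cfg = SimConfig(n=250, nEu=3e-3, planted=planted, seed=100 + t, cancer_type=label)
    table, _ = simulate_cohort(cfg, model)
    annotated = annotate_mutations(table, model)
    specs.append(tally_spectrum(annotated, count_sites(model), cfg.n, label))

matrix = build_site_matrix(specs)
stats, summary = sharing_stats(matrix, {s.cancer_type: 3 for s in specs})
for key in (shared, private):
    row = stats.loc[key]
    print(
        f"{key}: i_max={row['i_max']}, observed in {row['NC']} type(s), "
        f"CDN in {row['n_cdn_types']}, class={row['sharing_class']}"
    )
print(f"sites per class: {summary.sites_per_class}")
print(f"per-site Pearson r (i_max vs CDN types, multi-type rows): {summary.r_per_site}")
print(
    "\nThe shared driver is a multi-type CDN; the private one reaches the"
    "\nthreshold in a single type even when sporadic hits appear elsewhere."
)
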