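# Demo pipeline configuration: every key is validated, unknown keys rejected.
# Thresholds are the published cutoffs; sizes are the demo cohort.
seed: 1
n_lines: 398
n_oc: 171
n_metabolites: 20
n_lipids: 30
marker_spacing_cM: 2.0
trait_h2: 0.55
lod_im: 2.5
lod_mls: 3.0
lod_qei: 5.0
flank_kb: 200.0
r_min: 0.8
ppi_min: 0.40
fimo_p: 1.0e-4
alpha: 0.05
ggm_alpha: 0.05
mcc_top: 0.10
min_cycle: 3
max_cycle: 5
stages: [simulate, assoc, qtl, annotate, grn, network]
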