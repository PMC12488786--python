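# Default synthetic scenario: a protective binary exposure, a 168-mediator
# metabolite panel with 95 truly exposure-associated members (one of them
# pleiotropic), two mediators of interest carrying the outcome paths, and
# 704 planted reverse-causality instances for the Steiger filter to remove.
# theta_total defaults to ln(0.956); the b for mediator 2 is scaled so the
# planted proportions mediated are 0.244 and 0.133.
seed: 7
alpha: 0.05
n_boot: 200

n_snv: 36
n_null_snv: 300
n_x: 440735
n_m: 115078
n_y: 138086
a_vec: [-0.06, -0.11]
b_vec: [0.183, 0.05440]
heterogeneity_scale: 1.5
f_true_range: [300.0, 2500.0]
mediator_f_range: [100.0, 200.0]
n_mediator_snv: 110

panel:
  n_mediators: 168
  n_true: 95
  n_reverse_instances: 704
  n_pleiotropic: 1
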