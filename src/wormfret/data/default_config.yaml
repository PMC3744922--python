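strains:
  N2:
    name: N2
    has_donor: false
    has_acceptor: false
    donor_fused_to_syn: false
    acceptor_fused_to_syn: false
    expresses_syn: false
  C:
    name: C
    has_donor: true
    has_acceptor: false
    donor_fused_to_syn: false
    acceptor_fused_to_syn: false
    expresses_syn: false
  V:
    name: V
    has_donor: false
    has_acceptor: true
    donor_fused_to_syn: false
    acceptor_fused_to_syn: false
    expresses_syn: false
  CV:
    name: CV
    has_donor: true
    has_acceptor: true
    donor_fused_to_syn: false
    acceptor_fused_to_syn: false
    expresses_syn: false
  C+V:
    name: C+V
    has_donor: true
    has_acceptor: true
    donor_fused_to_syn: false
    acceptor_fused_to_syn: false
    expresses_syn: false
  S+V:
    name: S+V
    has_donor: false
    has_acceptor: true
    donor_fused_to_syn: false
    acceptor_fused_to_syn: false
    expresses_syn: true
  SC:
    name: SC
    has_donor: true
    has_acceptor: false
    donor_fused_to_syn: true
    acceptor_fused_to_syn: false
    expresses_syn: true
  SV:
    name: SV
    has_donor: false
    has_acceptor: true
    donor_fused_to_syn: false
    acceptor_fused_to_syn: true
    expresses_syn: true
  SC+SV:
    name: SC+SV
    has_donor: true
    has_acceptor: true
    donor_fused_to_syn: true
    acceptor_fused_to_syn: true
    expresses_syn: true
donor_level: {}
acceptor_level: {}
default_expression_level: 1.0
expression_growth:
  L4: 1.0
  day1: 1.1
  day6: 1.31
fret_yield:
  L4: 0.5
  day1: 0.56
  day6: 0.6946564885496184
crossover_true:
  alpha: 0.45
  beta: 0.07
channel_cv: 0.05
worms_per_well_target: 1250
worms_per_well_bounds:
- 1000
- 1500
dispense_cv: 0.02
replicates: 4
trait_means:
  dev_time_h: 74.0
  brood_size: 284.2
  pumps_per_min: 195.8
  bends_per_30s: 14.2
trait_sds:
  dev_time_h: 3.0
  brood_size: 45.7
  pumps_per_min: 5.2
  bends_per_30s: 1.5
syn_trait_effects:
  dev_time_h: 1.0
  brood_size: 1.0
  pumps_per_min: 0.82
  bends_per_30s: 0.5
lifespan_mean_days: 17.0
lifespan_sd_days: 3.0
syn_lifespan_shift_days: -5.0
marker_lifespan_shift_days: -1.5
seed: null
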