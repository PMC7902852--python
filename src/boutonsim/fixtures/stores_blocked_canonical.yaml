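name: stores_blocked_canonical
compartments:
- name: bulk
  volume_um3: 0.9359999999999999
  initial_free_ca_M: 1.0e-07
  is_reservoir: false
- name: az
  volume_um3: 0.005
  initial_free_ca_M: 1.0e-07
  is_reservoir: false
- name: vdcc
  volume_um3: 0.02
  initial_free_ca_M: 1.0e-07
  is_reservoir: false
- name: er
  volume_um3: 0.03900000000000001
  initial_free_ca_M: 0.0
  is_reservoir: false
- name: ext
  volume_um3: 1.0
  initial_free_ca_M: 0.002
  is_reservoir: true
populations:
- label: vdcc
  scheme_name: vdcc
  count: 80
  sensed_compartment: vdcc
  luminal_compartment: null
  flux_target: vdcc
- label: ryr
  scheme_name: ryr
  count: 40
  sensed_compartment: vdcc
  luminal_compartment: er
  flux_target: vdcc
- label: ip3r
  scheme_name: ip3r
  count: 20
  sensed_compartment: bulk
  luminal_compartment: er
  flux_target: bulk
- label: serca
  scheme_name: serca
  count: 0
  sensed_compartment: bulk
  luminal_compartment: er
  flux_target: null
- label: serca@vdcc
  scheme_name: serca
  count: 0
  sensed_compartment: vdcc
  luminal_compartment: er
  flux_target: null
- label: pmca
  scheme_name: pmca
  count: 1530
  sensed_compartment: bulk
  luminal_compartment: null
  flux_target: null
- label: sensor
  scheme_name: sensor
  count: 7
  sensed_compartment: az
  luminal_compartment: null
  flux_target: null
- label: calbindin@bulk
  scheme_name: calbindin
  count: 25365
  sensed_compartment: bulk
  luminal_compartment: null
  flux_target: null
- label: calbindin@az
  scheme_name: calbindin
  count: 135
  sensed_compartment: az
  luminal_compartment: null
  flux_target: null
- label: calbindin@vdcc
  scheme_name: calbindin
  count: 542
  sensed_compartment: vdcc
  luminal_compartment: null
  flux_target: null
exchange:
- comp_a: vdcc
  comp_b: bulk
  conductance_um3_per_s: 25.0
- comp_a: vdcc
  comp_b: az
  conductance_um3_per_s: 1.1
- comp_a: az
  comp_b: bulk
  conductance_um3_per_s: 16.0
ca_out_M: 0.002
rrp_size: 7
rrp_refill_rate_per_s: 0.34
ip3_M: 0.0
stores_blocked: true
leak_site_count: 1254
rate_overrides: {}
rng_seed: 0
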