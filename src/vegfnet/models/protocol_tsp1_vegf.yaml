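# Standard inhibition protocol: 2 nM TSP1 for 10 min, then 50 ng/ml VEGF
# for 40 min, with the combined TSP1/CD47 mechanism dialed in.
duration_min: 50
dt_out_s: 5
equilibrate: true
events:
  - time_min: 0
    set_ligand: TSP1
    value: 2
    unit: nM
  - time_min: 10
    set_ligand: VEGF
    value: 50
    unit: ng/ml
overrides:
  fold_deg: 10
  fold_dp: 51
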