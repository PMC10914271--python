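# Empirical NSCLC/gefitinib therapy simulation parameters
mutation_rate: 1.0e-3        # per site per division
init_mutant_prob: 0.1        # pre-existing heterogeneity (~10% mutants)
death_rate: 0.025            # per hour
init_density: 0.1            # log-midpoint of the plausible 0.01-1 range
init_shape: square
init_side: 100
vessel_conc: 10.0            # ug/mL at the vessel boundary
n_steps: 2016                # hours (12 weeks)
dt: 1.0
net_loss_threshold: 0.80442  # ug/mL; 1.8 uM gefitinib (MW 446.9 g/mol)
grid_shape: [100, 100]
vessels: [[50, 25], [50, 75]]
length_scales: [2, 4, 8, 16] # characteristic penetration lengths, lattice units
replicates: 10
schedule:
  n_cycles: 4
  on_hours: 168
  off_hours: 168
  tail_off_hours: 672
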