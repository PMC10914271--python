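# Synthetic-seascape simulation parameters (gamma sweep / entropy experiments)
mutation_rate: 1.0e-4        # per site per division
init_mutant_prob: 0.01
death_rate: 0.1              # per hour
init_density: 1.0
init_shape: circle
init_radius: 10.0
vessel_conc: 1000.0          # ug/mL at the vessel boundary
diffusion_rate: 0.1          # lattice units^2 per hour
n_steps: 1000                # hours
dt: 1.0
grid_shape: [100, 100]
vessels: [[50, 25], [50, 75]]
gammas: [1.0e-4, 1.0e-3, 1.0e-2, 1.0e-1, 0.5]
replicates: 10
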