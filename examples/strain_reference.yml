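# Reference-strain simulator configuration (generator defaults, spelled out).
# Positions/lengths in bp, times in minutes, speeds in bp/min.
seed: 1
locus_length: 60000
bin_width: 50
origins:
  - [5000, 10.0, 2.0]    # early origin: position, firing mean, firing sd
  - [55000, 50.0, 5.0]   # late converging origin
fork_speed: 1000.0
barrier_pos: 30000
p_block: 0.9             # probability a rightward fork arrests at the barrier
p_restart: 0.9           # probability an arrested fork restarts
restart_delay: 20.0      # minutes from arrest to restart
restart_speed: 1000.0    # speed of the restarted (delta/delta) fork
resection_len: 1000      # nascent strand resected and re-synthesized delta/delta
background: 0.05         # ribonucleotide signal from the non-mutated polymerase
depth: 100.0             # expected counts per bin per library at usage 1
n_cells: 5000
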