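# Example pipeline configuration: simulate a winter capture campaign and
# run the full recovery analysis.  All thresholds default to the study
# protocol (6 fixes / 24 h, 72 h max gap, >= 20 d monitoring, first fix
# within 3 d, home-range window days 11-21 with >= 10 locations).

seed = 1
out_dir = "results/example_run"

# To analyse real fix tables instead, drop the [simulation] block and set:
# fixes_path = "fixes.csv"
# captures_path = "captures.csv"

[simulation]
n_animals = 40
season_start = "2021-10-03"
season_end = "2022-03-25"
fix_interval_h = 4.0
ou_sd_m = 150.0          # stationary positional SD (~30 ha home range)
ou_timescale_h = 12.0
cog_shift_m = 300.0      # initial outward shift of the range, metres
cog_decay_days = 5.0
step_suppression = 0.5   # steps halved immediately after release
step_decay_days = 5.0
fix_loss_prob = 0.1
obs_noise_m = 15.0
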