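# Five-condition artifact-matrix experiment at the default study conditions.
# Run with:  epighost run --config examples/experiment.toml

seed = 1
noise_sd = 0.0

[protocol]
fov_m = 0.1
matrix_read = 96
matrix_phase = 96
echo_spacing_s = 1.0e-3
gmax_mTm = 80.0
slew_Tms = 200.0

[girf]
preset = "shim_coupled"

[scene]
matrix = 96
coils = 8

[[conditions]]
name = "A_no_ramp"
ramp_sampling = false

[[conditions]]
name = "B_ramp"
ramp_sampling = true

[[conditions]]
name = "C_ramp_grappa"
ramp_sampling = true
grappa = 3

[[conditions]]
name = "D_poor_shim_no_ramp"
ramp_sampling = false
shim_quality = "poor"

[[conditions]]
name = "E_ramp_dual_polarity"
ramp_sampling = true
dual_polarity = true
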