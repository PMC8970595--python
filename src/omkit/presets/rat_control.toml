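# Rat left-ventricle pacing scenario.  The raw-SNR calibration (1.4) is the
# published rat figure; the APD80 and velocities are declared defaults (the
# source measurements print no absolute rat APD or CV).

name = "rat_control"

[camera]
width = 200
height = 200
frame_rate = 977.0
bits_per_sample = 10
duration_ms = 2000.0
pixel_size = 0.035

[wave]
pacing_site = "center"
v_long = 0.55
v_trans = 0.30
long_axis_angle = 20.0
pcl = 150.0

[ap]
apd80 = 60.0
upstroke_duration = 2.0
amplitude_fraction = 0.05
restitution_slope = 0.2
drug_apd_increment = 0.0
drug = false

[noise]
baseline_intensity = 600.0
vignette_strength = 0.3
target_raw_snr = 1.4
drift_per_second = 2.0
seed = 0

[conditioning]
spatial_window = 5
spatial_sigma = 1.0
ensemble_window_ms = 2000.0
diastolic_fraction = 0.2
snr_cutoff = 2.0
intensity_cutoff = 480.0
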