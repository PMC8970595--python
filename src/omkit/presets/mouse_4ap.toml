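# Mouse scenario with the potassium-current blocker emulated as a fixed
# +19 ms APD80 increment; otherwise identical to mouse_control.

name = "mouse_4ap"

[camera]
width = 200
height = 200
frame_rate = 977.0
bits_per_sample = 10
duration_ms = 2000.0
pixel_size = 0.035

[wave]
pacing_site = "center"
v_long = 0.51
v_trans = 0.29
long_axis_angle = 20.0
cv_slope_long_per_ms = 0.000666666666667   # m/s per ms PCL: 51 -> 47 cm/s over 150 -> 90 ms
cv_slope_trans_per_ms = 0.000666666666667  # 29 -> 25 cm/s over the same span
pcl = 150.0

[ap]
apd80 = 40.0
upstroke_duration = 2.0
amplitude_fraction = 0.05
restitution_slope = 0.271428571428571
drug_apd_increment = 19.0
drug = true

[noise]
baseline_intensity = 600.0
vignette_strength = 0.3
target_raw_snr = 0.5
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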