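# Mouse left-ventricle pacing scenario, control conditions.
# Velocities and the restitution/drug anchors follow the published rodent
# measurements this simulator emulates; the absolute APD80 and the camera
# calibration (pixel size, baseline counts) are declared defaults.

name = "mouse_control"

[camera]
width = 200
height = 200
frame_rate = 977.0
bits_per_sample = 10
duration_ms = 2000.0
pixel_size = 0.035      # mm/px

[wave]
pacing_site = "center"
v_long = 0.51           # m/s at PCL 150 ms
v_trans = 0.29          # m/s
long_axis_angle = 20.0  # degrees from +x (columns)
cv_slope_long_per_ms = 0.000666666666667   # m/s per ms PCL: 51 -> 47 cm/s over 150 -> 90 ms
cv_slope_trans_per_ms = 0.000666666666667  # 29 -> 25 cm/s over the same span
pcl = 150.0             # ms

[ap]
apd80 = 40.0                  # ms at PCL 150 (declared default)
upstroke_duration = 2.0       # ms
amplitude_fraction = 0.05     # dF/F
restitution_slope = 0.271428571428571  # 19 ms over the 150->80 ms PCL span
drug_apd_increment = 19.0     # ms (4-AP emulation)
drug = false

[noise]
baseline_intensity = 600.0    # counts (10-bit range 0..1023)
vignette_strength = 0.3
target_raw_snr = 0.5          # masked-mean raw SNR calibration
drift_per_second = 2.0        # counts/s
seed = 0

[conditioning]
spatial_window = 5
spatial_sigma = 1.0
ensemble_window_ms = 2000.0
diastolic_fraction = 0.2
snr_cutoff = 2.0
intensity_cutoff = 480.0      # counts; 0.8 x center baseline
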