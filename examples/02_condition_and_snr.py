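"""Condition a noisy recording and measure the SNR gain.

Simulates the down-scaled mouse scenario, runs the conditioning chain
(5x5 spatial gaussian, beat segmentation, ensemble averaging over the 2 s
window) and compares raw vs conditioned signal-to-noise ratio, computed as
RMS signal amplitude over RMS diastolic noise.
"""
import omkit

scenario = omkit.load_scenario("mouse_control", shape=(100, 100), seed=0)
recording, truth = scenario.simulate()

params = omkit.ConditioningParams(
    pcl=scenario.wave.pcl,
    spatial_window=scenario.spatial_window,
    intensity_cutoff=scenario.intensity_cutoff,
)
cond = omkit.condition_recording(recording, params)

m = cond.mask.keep
raw = cond.snr_raw.masked_mean(m)
conditioned = cond.snr_conditioned.masked_mean(m)
print(f"{cond.beat.n_beats_averaged} beats averaged over the 2 s window")
print(f"mask keeps {cond.mask.n_kept} of {m.size} pixels "
      f"(SNR >= {params.snr_cutoff}, intensity >= {params.intensity_cutoff:.0f} counts)")
print(f"raw SNR (masked mean):         {raw:5.2f}   <- noise dominates the dye signal")
print(f"conditioned SNR (masked mean): {conditioned:5.2f}   <- after binning + averaging")
print(f"gain: {conditioned / raw:.1f}x "
      f"(~3.5x from 5x5 spatial binning, ~sqrt(13) from 13-beat averaging)")
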