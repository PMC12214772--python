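"""Design a Pong scan and compare its coverage with a raster scan.

Builds the default 200 µm / 0.8 µm / 667 Hz configuration, quantises the
galvo waveforms to prime FPGA counters, and measures how quickly each scan
visits the pixels of the field.
"""

from pongscope import scan

cfg = scan.ScanConfig()
x_freq, y_freq = scan.nominal_frequencies(cfg)
wx, wy = scan.quantize_counters(cfg, x_freq, y_freq)
tau = scan.raster_characteristic_time(cfg, x_freq)

print(f"x frequency          : {x_freq:.1f} Hz (counter {wx.counter}, "
      f"effective {wx.freq_effective:.1f} Hz)")
print(f"y frequency          : {y_freq:.1f} Hz (counter {wy.counter}, "
      f"effective {wy.freq_effective:.1f} Hz)")
print(f"raster time tau      : {tau * 1e3:.0f} ms   "
      "(time for a bi-directional raster to sample the field once)")
print(f"movie time step      : {tau / 2 * 1e3:.0f} ms   (tau/2)")

pong = scan.pong_trajectory(cfg, 2.6 * tau)
raster = scan.raster_trajectory(cfg, 1.05 * tau)
for pixel in (2.0, cfg.dx):
    p = scan.coverage_stats(pong, pixel, tau / 2).fraction_visited
    r = scan.coverage_stats(raster, pixel, tau / 2).fraction_visited
    print(f"coverage at {pixel:.1f} µm pixels after tau/2: "
          f"pong {p:.2f} vs raster {r:.2f}")
t_full = scan.time_to_full_coverage(pong, cfg.dx)
print(f"pong time to full {cfg.dx:.1f} µm coverage: {t_full / tau:.2f} tau "
      "(a raster needs 1.0 tau; the Pong scan trades this redundancy for "
      "uniform, continual revisiting of the whole field)")
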