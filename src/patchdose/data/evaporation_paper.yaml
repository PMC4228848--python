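# Cumulative evaporative H2S loss anchors (time in minutes, loss fraction).
# ~35% lost during the first 5 min of solution handling, ~7% more over the
# 5-min application window, 42% total by 20 min; held constant thereafter.
anchors:
  - {t_min: 0.0, loss: 0.0}
  - {t_min: 5.0, loss: 0.35}
  - {t_min: 10.0, loss: 0.42}
  - {t_min: 20.0, loss: 0.42}
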