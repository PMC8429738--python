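{
  "height": {"beta0": 11.3263, "beta1": 0.5256, "beta2": -0.0227},
  "width": {"beta0": -8.3606, "beta1": 2.8362, "beta2": -0.0896},
  "perimeter": {"beta0": -10.7224, "beta1": 2.6182, "beta2": -0.0295},
  "left_diagonal": {"beta0": -24.5070, "beta1": 7.2812, "beta2": -0.3314},
  "right_diagonal": {"beta0": -4.2913, "beta1": 3.4149, "beta2": -0.1534}
}
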