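# Default augmentation schedule for training-set expansion.
# Geometric operations warp image and mask together; photometric operations
# touch the image only.  Likelihoods are independent per operation.
operations:
  - name: horizontal_flip
    params: {}
    likelihood: 0.5
  - name: rotate
    params:
      limit_deg: [-90.0, 90.0]
    likelihood: 1.0
  - name: gaussian_noise
    params:
      mean: 0.0
      std_choices: [0.01, 0.05]
    likelihood: 0.2
  - name: photometric_oneof
    params:
      choices: [clahe, brightness, gamma, contrast]
      clahe:
        clip_limit: 0.04
        kernel: [8, 8]
      brightness:
        limit: [-0.2, 0.2]
      gamma:
        range: [0.8, 1.2]
      contrast:
        range: [0.8, 1.2]
    likelihood: 0.9
  - name: hsv_shift
    params:
      h_limit: 20
      s_limit: 30
      v_limit: 20
    likelihood: 0.9
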