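{
  "description": "Monte-Carlo quantiles of sup_s ||B_d(s)||^2 (d-dim standard Brownian bridge)",
  "reps": 200000,
  "grid_size": 2000,
  "seed": 20200424,
  "values": {
    "1": {
      "0.10": 1.4634,
      "0.05": 1.8029,
      "0.01": 2.5991
    },
    "2": {
      "0.10": 2.0745,
      "0.05": 2.462,
      "0.01": 3.3721
    },
    "3": {
      "0.10": 2.5749,
      "0.05": 3.0065,
      "0.01": 3.9522
    },
    "4": {
      "0.10": 3.0457,
      "0.05": 3.4969,
      "0.01": 4.4762
    },
    "5": {
      "0.10": 3.4652,
      "0.05": 3.9451,
      "0.01": 4.9797
    },
    "6": {
      "0.10": 3.878,
      "0.05": 4.3864,
      "0.01": 5.463
    }
  }
}
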