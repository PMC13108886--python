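{
 "variant": "B",
 "parameters": {
  "k1": 9.976730132869477,
  "k2": 0.10730725031205757,
  "k3": 2.280254510216911,
  "k4": 0.536886453581368,
  "k5": 3.6009985573473435,
  "k6": 9.080439752918966,
  "k7": 6.573772013583345,
  "k8": 6.533489850449805,
  "k9": 8.842456994788495,
  "k10": 0.3231378715594598,
  "k11": 0.43714446339695007,
  "k12": 0.9261080466234564,
  "k13": 0.11307832299874723,
  "k14": 8.384833162250219,
  "k15": 9.0432510858003,
  "k16": 0.3234918222922936,
  "k17": 7.569978203542417,
  "k18": 0.6634747924791318,
  "k19": 0.6433093192254887,
  "k20": 2.2700114110840124,
  "k21": 0.2501072930084241,
  "k22": 1.133335878982408,
  "k23": 3.907153800409017,
  "k24": 0.5003939910325865,
  "k25": 0.1002235132295419,
  "k26": 0.3481279364552754,
  "k27": 0.2964215953587425,
  "k28": 5.235734005164879,
  "k29": 3.56766623837406
 }
}
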