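{
  "affinity_witness": {
    "F_at_ultra": 0.863648157354562,
    "adaptive_idx": 0,
    "ultra_idx": 2,
    "w_at_adaptive": 0.3271366830958906
  },
  "provenance": {
    "method": "saturated-regime screen candidates refined by a seeded stochastic hill-climb on min(best-F/0.8, best-w/0.3) over a scaffold-concentration grid; T_total pinned at the sweep's adaptive grid point",
    "refine_objective": 1.0804596725875049,
    "screen_regime": "saturated"
  },
  "rates": {
    "k1": 999.9999999999998,
    "k10": 0.0026008084442009157,
    "k2": 0.5015474968723063,
    "k3": 10.174476239951897,
    "k4": 999.9999999999998,
    "k5": 0.0010000000000000002,
    "k6": 1.5698094100907167,
    "k7": 1.1327329066251453,
    "k8": 0.0010000000000000002,
    "k9": 87.79079670601314
  },
  "sweep_seed": 0,
  "t_sweep_witness": {
    "F_at_ultra": 0.8643677380700039,
    "adaptive_idx": 40,
    "ultra_idx": 0,
    "w_at_adaptive": 0.3271366830958906
  },
  "totals": {
    "P_total": 0.1,
    "S_total": 1.0,
    "T_total": 0.1494869133709233
  }
}
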