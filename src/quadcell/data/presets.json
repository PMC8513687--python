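{
  "schema": "quadcell-presets-1",
  "presets": {
    "PACED_BEAT": {
      "description": "Paced monolayer beat at 0.5 Hz: contraction peak 190.3 ms after the stimulus with 13.2 ms beat-to-beat sd.",
      "authoritative": ["ct_pk_ms", "jitter_sd_ms", "protocol"],
      "beat": {
        "amplitude_au": 1.0,
        "ct_prime_pk_ms": 125.73,
        "ct_pk_ms": 190.3,
        "rx_prime_pk_ms": 277.41,
        "t_d_ms": 429.81,
        "jitter_sd_ms": 13.2
      },
      "protocol": {
        "amplitude_uA": 8.0,
        "pulse_width_ms": 1.2,
        "frequency_hz": 0.5,
        "n_pulses": 10
      },
      "notes": "CT', RX' and T_d are the BASELINE_0NM shape scaled by 190.3/211.9; only the contraction peak time and its sd are measured values."
    },
    "BASELINE_0NM": {
      "description": "Multi-parametric baseline (no isoproterenol), paced at 1 Hz, n = 19 beats.",
      "authoritative": ["ct_pk_ms", "rx_prime_pk_ms", "t_d_ms", "ep.fpd_ms", "sigma", "n_beats", "dose_nM"],
      "dose_nM": 0.0,
      "n_beats": 19,
      "beat": {
        "amplitude_au": 1.0,
        "ct_prime_pk_ms": 140.0,
        "ct_pk_ms": 211.9,
        "rx_prime_pk_ms": 308.9,
        "t_d_ms": 478.6,
        "jitter_sd_ms": 9.1
      },
      "sigma": {"ct_pks_ms": 9.1, "rx_prime_pks_ms": 16.5, "t_d_ms": 23.6},
      "ep": {
        "t_ap_ms": 13.6,
        "spike_amp_uv": 100.0,
        "fpd_ms": 238.6,
        "artefact_amp_uv": 2000.0,
        "twave_width_ms": 80.0,
        "twave_amp_uv": 30.0,
        "noise_sd_uv": 0.0
      },
      "protocol": {
        "amplitude_uA": 33.0,
        "pulse_width_ms": 1.2,
        "frequency_hz": 1.0,
        "n_pulses": 19
      },
      "notes": "CT' is not a measured value (design choice); t_ap from the 678 um electrode separation at 50 um/ms conduction; artefact/T-wave scales are representative, not measured."
    },
    "ISO_3NM": {
      "description": "3 nM isoproterenol: all cyclic-process features shortened, n = 19 beats.",
      "authoritative": ["ct_pk_ms", "rx_prime_pk_ms", "t_d_ms", "ep.fpd_ms", "n_beats", "dose_nM"],
      "dose_nM": 3.0,
      "n_beats": 19,
      "beat": {
        "amplitude_au": 1.0,
        "ct_prime_pk_ms": 137.03,
        "ct_pk_ms": 207.4,
        "rx_prime_pk_ms": 302.4,
        "t_d_ms": 424.6,
        "jitter_sd_ms": 9.1
      },
      "sigma": {"ct_pks_ms": 9.1, "rx_prime_pks_ms": 16.5, "t_d_ms": 23.6},
      "ep": {
        "t_ap_ms": 13.6,
        "spike_amp_uv": 100.0,
        "fpd_ms": 226.2,
        "artefact_amp_uv": 2000.0,
        "twave_width_ms": 80.0,
        "twave_amp_uv": 30.0,
        "noise_sd_uv": 0.0
      },
      "protocol": {
        "amplitude_uA": 33.0,
        "pulse_width_ms": 1.2,
        "frequency_hz": 1.0,
        "n_pulses": 19
      },
      "notes": "Per-feature sd values carried over from baseline (not separately reported)."
    },
    "ISO_10NM": {
      "description": "10 nM isoproterenol: a further proportional shortening of every feature. SYNTHETIC DEFAULTS: the 10 nM values appear only graphically in the source study and are NOT authoritative.",
      "authoritative": ["n_beats", "dose_nM"],
      "dose_nM": 10.0,
      "n_beats": 19,
      "beat": {
        "amplitude_au": 1.0,
        "ct_prime_pk_ms": 134.12,
        "ct_pk_ms": 203.0,
        "rx_prime_pk_ms": 296.04,
        "t_d_ms": 376.69,
        "jitter_sd_ms": 9.1
      },
      "sigma": {"ct_pks_ms": 9.1, "rx_prime_pks_ms": 16.5, "t_d_ms": 23.6},
      "ep": {
        "t_ap_ms": 13.6,
        "spike_amp_uv": 100.0,
        "fpd_ms": 214.44,
        "artefact_amp_uv": 2000.0,
        "twave_width_ms": 80.0,
        "twave_amp_uv": 30.0,
        "noise_sd_uv": 0.0
      },
      "protocol": {
        "amplitude_uA": 33.0,
        "pulse_width_ms": 1.2,
        "frequency_hz": 1.0,
        "n_pulses": 19
      },
      "notes": "Each feature shortened again by its own 3 nM / 0 nM ratio."
    },
    "ARP_222": {
      "description": "Monolayer with a 222 ms absolute refractory period (50 % capture at 9 Hz).",
      "authoritative": ["arp_ms"],
      "arp_ms": 222.0
    },
    "FIBROBLAST_TIMELAPSE": {
      "description": "Two fibroblast aggregates pipetted at t = 0 (left) and t = 39 h (top); adhesion plateau 1.0-1.2 MOhm; trypsin detachment slow at room temperature, fast at 37 C.",
      "authoritative": ["impedance_plateau_ohm (range)", "aggregate seed times", "detachment phases"],
      "timelapse": {
        "aggregates": [
          {"centre_rc": [16, 6], "seed_time_h": 0.0, "initial_radius_um": 220.0, "growth_rate_um_per_h": 6.0, "opacity_decay_per_h": 0.012},
          {"centre_rc": [6, 16], "seed_time_h": 39.0, "initial_radius_um": 300.0, "growth_rate_um_per_h": 6.0, "opacity_decay_per_h": 0.012}
        ],
        "impedance_base_ohm": 250000.0,
        "impedance_plateau_ohm": 1100000.0,
        "adhesion_tau_h": 6.0,
        "seed": 0
      },
      "detachment": {
        "start_min": 8520.0,
        "rate_rt_per_min": 0.01,
        "rate_37c_per_min": 0.15,
        "incubation_start_min": 8531.0
      }
    },
    "CARDIO_SPHEROID_TIMELAPSE": {
      "description": "Cardiomyocyte spheroids, slight spreading over 96 h; adhesion plateau 0.5-0.8 MOhm.",
      "authoritative": ["impedance_plateau_ohm (range)"],
      "timelapse": {
        "aggregates": [
          {"centre_rc": [10, 10], "seed_time_h": 0.0, "initial_radius_um": 130.0, "growth_rate_um_per_h": 1.5, "opacity_decay_per_h": 0.0},
          {"centre_rc": [22, 20], "seed_time_h": 0.0, "initial_radius_um": 110.0, "growth_rate_um_per_h": 1.5, "opacity_decay_per_h": 0.0}
        ],
        "impedance_base_ohm": 250000.0,
        "impedance_plateau_ohm": 650000.0,
        "adhesion_tau_h": 8.0,
        "seed": 0
      }
    }
  }
}
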